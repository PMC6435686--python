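"""Fusion-gene and MET exon-14-skipping calling from NanoString probe counts.

A fusion transcript is driven by the partner gene's promoter, so probes on
the kinase (3') side of the target gene report much higher counts than 5'
probes: the 3'/5' imbalance ratio flags a fusion, and variant-specific
junction probes (e.g. EML4-ALK_E13:A20) pin down the breakpoint.  A call is
positive only in the "upper right quadrant": imbalance ratio AND best
junction count both above threshold.  MET exon 14 skipping is called
analogously from the exon 13-15 junction probe (y) against the ratio of
flanking-exon (3-4, 20-21) to exon-14 expression (x).

The quadrant geometry comes from the assay design; the numeric cutoffs are
configuration (defaults: ratio >= 2, junction >= 50 counts) and should be
calibrated per panel.  Calls are per-gene independent, so one sample may be
positive for several targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import ExpressionMatrix


@dataclass(frozen=True)
class GeneProbeSet:
    """Probe roles for one fusion target gene."""

    gene: str
    five_prime_probes: tuple[str, ...]
    three_prime_probes: tuple[str, ...]
    variant_junction_probes: Mapping[str, str]  # variant name -> probe id, panel order

    def __post_init__(self) -> None:
        groups = [set(self.five_prime_probes), set(self.three_prime_probes),
                  set(self.variant_junction_probes.values())]
        for i in range(3):
            for j in range(i + 1, 3):
                if groups[i] & groups[j]:
                    raise ValueError(f"probe id sets overlap within gene {self.gene!r}")


@dataclass(frozen=True)
class MetProbeSet:
    """MET exon probes: flanking groups, exon 14, and the exon 13-15 skip junction."""

    exons_3_4: tuple[str, ...]
    exon_14: str
    exons_20_21: tuple[str, ...]
    skip_junction_probe: str

    def __post_init__(self) -> None:
        if not self.exons_3_4 or not self.exons_20_21:
            raise ValueError("MET needs both flanking exon probe groups")


@dataclass(frozen=True)
class FusionProbePanel:
    genes: Mapping[str, GeneProbeSet]
    met: MetProbeSet | None = None
    positive_control_ids: tuple[str, ...] = ()


@dataclass
class FusionCall:
    sample_id: str
    gene: str
    status: str                      # positive | negative | inconclusive
    best_variant: str | None
    imbalance_ratio: float
    max_junction_count: float
    qc_flag: str                     # "pass" or "fail:<reason>"

    def __post_init__(self) -> None:
        if self.status not in ("positive", "negative", "inconclusive"):
            raise ValueError(f"bad status {self.status!r}")
        if self.status == "positive" and self.best_variant is None:
            raise ValueError("positive call requires best_variant")
        if self.status == "inconclusive" and self.qc_flag == "pass":
            raise ValueError("inconclusive call must carry a failing qc_flag")


@dataclass(frozen=True)
class FusionThresholds:
    """Quadrant cutoffs and QC gates; ratios are scale-free, junction counts absolute."""

    ratio_min: float = 2.0
    junction_min: float = 50.0
    flank_ratio_min: float = 2.0
    total_count_min: float = 100.0
    poscon_min: float = 8.0


def default_fusion_panel() -> FusionProbePanel:
    """Probe panel covering ALK, RET, ROS1, NRG1, NTRK1 fusions and MET exon 14."""
    return FusionProbePanel(
        genes={
            "ALK": GeneProbeSet(
                "ALK",
                five_prime_probes=("ALK_5p_1", "ALK_5p_2", "ALK_5p_3"),
                three_prime_probes=("ALK_3p_1", "ALK_3p_2", "ALK_3p_3"),
                variant_junction_probes={
                    "EML4-ALK_E6B:A20": "ALK_jx_E6B_A20",
                    "EML4-ALK_E13:A20": "ALK_jx_E13_A20",
                    "EML4-ALK_E20:A20": "ALK_jx_E20_A20",
                },
            ),
            "RET": GeneProbeSet(
                "RET",
                five_prime_probes=("RET_5p_1", "RET_5p_2"),
                three_prime_probes=("RET_3p_1", "RET_3p_2"),
                variant_junction_probes={
                    "KIF5B-RET_K15:R12": "RET_jx_K15_R12",
                    "KIF5B-RET_K16:R12": "RET_jx_K16_R12",
                },
            ),
            "ROS1": GeneProbeSet(
                "ROS1",
                five_prime_probes=("ROS1_5p_1", "ROS1_5p_2"),
                three_prime_probes=("ROS1_3p_1", "ROS1_3p_2"),
                variant_junction_probes={
                    "CD74-ROS1_C6:R34": "ROS1_jx_C6_R34",
                    "SLC34A2-ROS1_S4:R32": "ROS1_jx_S4_R32",
                },
            ),
            "NRG1": GeneProbeSet(
                "NRG1",
                five_prime_probes=("NRG1_5p_1", "NRG1_5p_2"),
                three_prime_probes=("NRG1_3p_1", "NRG1_3p_2"),
                variant_junction_probes={"CD74-NRG1_C8:N6": "NRG1_jx_C8_N6"},
            ),
            "NTRK1": GeneProbeSet(
                "NTRK1",
                five_prime_probes=("NTRK1_5p_1", "NTRK1_5p_2"),
                three_prime_probes=("NTRK1_3p_1", "NTRK1_3p_2"),
                variant_junction_probes={"TPM3-NTRK1_T7:N10": "NTRK1_jx_T7_N10"},
            ),
        },
        met=MetProbeSet(
            exons_3_4=("MET_ex3_1", "MET_ex4_1"),
            exon_14="MET_ex14_1",
            exons_20_21=("MET_ex20_1", "MET_ex21_1"),
            skip_junction_probe="MET_jx_ex13_15",
        ),
        positive_control_ids=("POS_A", "POS_B", "POS_C"),
    )


def load_fusion_panel(path) -> FusionProbePanel:
    """Load a probe panel from YAML/JSON (keys: genes, met, positive_controls)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    genes = {
        g: GeneProbeSet(
            g,
            five_prime_probes=tuple(e["five_prime"]),
            three_prime_probes=tuple(e["three_prime"]),
            variant_junction_probes=dict(e.get("variants", {})),
        )
        for g, e in raw.get("genes", {}).items()
    }
    met = None
    if "met" in raw:
        m = raw["met"]
        met = MetProbeSet(
            exons_3_4=tuple(m["exons_3_4"]),
            exon_14=str(m["exon_14"]),
            exons_20_21=tuple(m["exons_20_21"]),
            skip_junction_probe=str(m["skip_junction_probe"]),
        )
    return FusionProbePanel(
        genes=genes, met=met,
        positive_control_ids=tuple(raw.get("positive_controls", ())),
    )


def _mean_counts(counts: pd.Series, probes: Sequence[str], trimmed: bool = False) -> float:
    vals = np.asarray([float(counts[p]) for p in probes])
    if trimmed and len(vals) >= 3:
        vals = np.sort(vals)[:-1]  # drop the highest probe (high-background outlier)
    return float(vals.mean())


def compute_imbalance_ratio(
    counts: pd.Series,
    entry: GeneProbeSet,
    trimmed_five_prime: bool = False,
) -> float:
    """3'/5' mean-count ratio for one sample; counts must be floored above 0.

    ``trimmed_five_prime`` drops the highest 5' probe before averaging, an
    optional guard against a single high-background 5' probe; off by default.
    """
    if not entry.five_prime_probes or not entry.three_prime_probes:
        raise ValueError(f"empty probe group for gene {entry.gene!r}")
    three = _mean_counts(counts, entry.three_prime_probes)
    five = _mean_counts(counts, entry.five_prime_probes, trimmed=trimmed_five_prime)
    if five <= 0:
        raise ValueError("5' mean is non-positive; background-correct with floor >= 1 first")
    return three / five


def qc_conclusive(
    counts: pd.Series,
    positive_control_ids: Sequence[str],
    total_count_min: float,
    poscon_min: float,
) -> tuple[bool, str]:
    """Sample-level QC gate: enough total signal and healthy positive controls.

    Returns (passed, reason); thresholds are inclusive (>= passes).  Failing
    QC makes every call for the sample inconclusive rather than negative —
    insufficient RNA must not masquerade as fusion-negative.
    """
    poscons = [p for p in positive_control_ids if p in counts.index]
    endo = counts.drop(index=poscons)
    if float(endo.sum()) < total_count_min:
        return False, "low_total_counts"
    if poscons:
        gm = float(np.exp(np.mean(np.log(np.maximum(counts[poscons].astype(float), 1e-12)))))
        # tolerate log/exp rounding so an exactly-at-threshold sample passes
        if gm < poscon_min and not np.isclose(gm, poscon_min, rtol=1e-9):
            return False, "low_positive_controls"
    return True, ""


def call_gene_fusion(
    sample_id: str,
    counts: pd.Series,
    entry: GeneProbeSet,
    thresholds: FusionThresholds = FusionThresholds(),
    qc_pass: bool = True,
    qc_reason: str = "",
    trimmed_five_prime: bool = False,
) -> FusionCall:
    """Upper-right-quadrant call for one gene in one sample.

    Positive iff the 3'/5' imbalance ratio >= ratio_min AND the best
    variant-junction count >= junction_min; the best variant is the argmax
    junction probe (ties to the first variant in panel order).
    """
    ratio = compute_imbalance_ratio(counts, entry, trimmed_five_prime)
    variants = list(entry.variant_junction_probes)
    jx = np.array([float(counts[entry.variant_junction_probes[v]]) for v in variants])
    best_i = int(jx.argmax()) if len(jx) else 0
    max_jx = float(jx[best_i]) if len(jx) else 0.0
    if not qc_pass:
        return FusionCall(sample_id, entry.gene, "inconclusive", None, ratio, max_jx,
                          f"fail:{qc_reason}")
    positive = ratio >= thresholds.ratio_min and max_jx >= thresholds.junction_min
    return FusionCall(
        sample_id, entry.gene,
        "positive" if positive else "negative",
        variants[best_i] if positive else None,
        ratio, max_jx, "pass",
    )


def call_met_exon14(
    sample_id: str,
    counts: pd.Series,
    met: MetProbeSet,
    thresholds: FusionThresholds = FusionThresholds(),
    qc_pass: bool = True,
    qc_reason: str = "",
) -> FusionCall:
    """Call MET exon 14 skipping from the exon 13-15 junction probe.

    x = mean(flanking exon 3-4 and 20-21 counts) / exon-14 count (floored),
    y = skip-junction count; positive iff x >= flank_ratio_min and
    y >= junction_min.
    """
    flank = _mean_counts(counts, tuple(met.exons_3_4) + tuple(met.exons_20_21))
    exon14 = max(float(counts[met.exon_14]), 1.0)
    x = flank / exon14
    y = float(counts[met.skip_junction_probe])
    if not qc_pass:
        return FusionCall(sample_id, "MET", "inconclusive", None, x, y, f"fail:{qc_reason}")
    positive = x >= thresholds.flank_ratio_min and y >= thresholds.junction_min
    return FusionCall(
        sample_id, "MET",
        "positive" if positive else "negative",
        "exon14_skipping" if positive else None,
        x, y, "pass",
    )


def call_cohort(
    matrix: ExpressionMatrix,
    panel: FusionProbePanel | None = None,
    thresholds: FusionThresholds = FusionThresholds(),
    trimmed_five_prime: bool = False,
) -> list[FusionCall]:
    """Run QC and all per-gene calls (plus MET) on every sample of a probe-count matrix."""
    panel = panel or default_fusion_panel()
    calls: list[FusionCall] = []
    for sid in matrix.sample_ids:
        counts = matrix.values[sid]
        ok, reason = qc_conclusive(
            counts, panel.positive_control_ids,
            thresholds.total_count_min, thresholds.poscon_min,
        )
        for gene in panel.genes:
            calls.append(
                call_gene_fusion(sid, counts, panel.genes[gene], thresholds,
                                 qc_pass=ok, qc_reason=reason,
                                 trimmed_five_prime=trimmed_five_prime)
            )
        if panel.met is not None:
            calls.append(call_met_exon14(sid, counts, panel.met, thresholds,
                                         qc_pass=ok, qc_reason=reason))
    return calls
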