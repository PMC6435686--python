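"""Synthetic NanoString-like cohorts with known truth.

Counts are drawn from a negative binomial (gamma-Poisson) to mimic the
overdispersion of nCounter data.  The histology generator emulates the
structure of a 68-tumor development cohort (27 AC, 30 SqCC, 11 LCNEC):
each sample's own-class marker genes are elevated, all other markers sit at
a low baseline, and optional "marker null" samples (LCC-like) express every
marker at baseline.  The fusion generator emulates the probe-count geometry
of fusion-positive samples — 3' probes amplified by a fold-change and the
true variant's junction probe lit up — with per-variant positive counts
defaulting to the composition observed in a 131-sample screen (five
EML4-ALK, four KIF5B-RET, two CD74-NRG1, three MET exon-14 skips).

Truth records are first-class outputs: downstream tests never re-derive
labels from the counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .fusion_caller import FusionProbePanel, default_fusion_panel
from .io_formats import ExpressionMatrix, Platform
from .ssp_core import MarkerPanel, default_marker_panel


def _nb_counts(rng: np.random.Generator, mean: float, size_param: float, n: int) -> np.ndarray:
    """Negative binomial via gamma-Poisson; size_param is the NB size (dispersion)."""
    lam = rng.gamma(shape=size_param, scale=mean / size_param, size=n)
    return rng.poisson(lam).astype(float)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic development cohort.

    ``n_per_class`` mirrors the 68-tumor development cohort; ``marker_mean_on``
    and ``marker_mean_off`` are NB means for a sample's own-class and
    other-class markers (counts); ``dispersion`` is the NB size parameter
    (smaller = noisier); ``marker_null_fraction`` adds LCC-like samples
    expressing all markers at the off level.
    """

    n_per_class: dict[str, int] = field(
        default_factory=lambda: {"AC": 27, "SqCC": 30, "LCNEC": 11}
    )
    marker_mean_on: float = 2000.0
    marker_mean_off: float = 50.0
    dispersion: float = 2.0
    negative_control_mean: float = 10.0
    n_negative_controls: int = 6
    marker_null_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_mean_on <= 0 or self.marker_mean_off <= 0 or self.negative_control_mean <= 0:
            raise ValueError("all means must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if any(n < 0 for n in self.n_per_class.values()):
            raise ValueError("class counts must be >= 0")
        if not 0 <= self.marker_null_fraction < 1:
            raise ValueError("marker_null_fraction must be in [0, 1)")


def simulate_histology_cohort(
    config: SimulationConfig | None = None,
    panel: MarkerPanel | None = None,
) -> tuple[ExpressionMatrix, pd.Series, pd.DataFrame]:
    """Draw a marker-gene cohort with class-specific elevation.

    Returns the count matrix (panel genes plus NEG_* negative-control
    probes), the sample labels, and a truth table (sample_id, true_class,
    marker_null).  Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    panel = panel or default_marker_panel()
    rng = np.random.default_rng(config.seed)
    genes = list(panel.genes)
    class_of_gene = {g: c for c, gs in panel.classes.items() for g in gs}

    sample_ids: list[str] = []
    labels: list[str] = []
    null_flags: list[bool] = []
    for cls, n in config.n_per_class.items():
        for i in range(n):
            sample_ids.append(f"S_{cls}_{i:03d}")
            labels.append(cls)
            null_flags.append(False)
    n_null = int(round(config.marker_null_fraction * len(sample_ids)))
    for i in range(n_null):
        sample_ids.append(f"S_LCC_{i:03d}")
        labels.append("LCC")
        null_flags.append(True)

    n = len(sample_ids)
    data = np.zeros((len(genes), n))
    for gi, g in enumerate(genes):
        own = class_of_gene[g]
        on = np.array([(lab == own) and not nul for lab, nul in zip(labels, null_flags)])
        data[gi, on] = _nb_counts(rng, config.marker_mean_on, config.dispersion, int(on.sum()))
        data[gi, ~on] = _nb_counts(rng, config.marker_mean_off, config.dispersion, int((~on).sum()))
    neg = np.vstack([
        _nb_counts(rng, config.negative_control_mean, config.dispersion, n)
        for _ in range(config.n_negative_controls)
    ])
    neg_ids = [f"NEG_{i + 1:02d}" for i in range(config.n_negative_controls)]
    df = pd.DataFrame(np.vstack([data, neg]), index=genes + neg_ids, columns=sample_ids)
    matrix = ExpressionMatrix(df, Platform.nanostring_counts)
    label_ser = pd.Series(labels, index=sample_ids, name="label")
    truth = pd.DataFrame(
        {"sample_id": sample_ids, "true_class": labels, "marker_null": null_flags}
    )
    return matrix, label_ser, truth


@dataclass(frozen=True)
class FusionSimulationConfig:
    """Conditions for the synthetic fusion-probe screen.

    ``positives_per_variant`` fixes how many samples carry each fusion
    variant (MET exon 14 skipping keyed ``MET_exon14``); the default mirrors
    a 131-sample screen with five ALK, four RET and two NRG1 fusions plus
    three MET skips.  ``three_prime_fold`` multiplies the 3' probe mean in
    fusion-positive samples; ``junction_mean_on`` is the lit junction probe's
    NB mean.  Signal probes use a tighter dispersion than background so the
    assay geometry, not simulator noise, drives the calls.
    """

    n_samples: int = 131
    positives_per_variant: dict[str, int] = field(
        default_factory=lambda: {
            "EML4-ALK_E6B:A20": 1,
            "EML4-ALK_E13:A20": 3,
            "EML4-ALK_E20:A20": 1,
            "KIF5B-RET_K15:R12": 2,
            "KIF5B-RET_K16:R12": 2,
            "CD74-NRG1_C8:N6": 2,
            "MET_exon14": 3,
        }
    )
    baseline_probe_mean: float = 500.0
    junction_background_mean: float = 2.0
    junction_mean_on: float = 2000.0
    three_prime_fold: float = 8.0
    exon14_suppression: float = 0.1
    dispersion: float = 2.0
    signal_dispersion: float = 10.0
    positive_control_mean: float = 300.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.three_prime_fold <= 0 or self.junction_mean_on <= 0:
            raise ValueError("fusion effect parameters must be positive")
        if sum(self.positives_per_variant.values()) > self.n_samples:
            raise ValueError("more positives requested than samples")


def simulate_fusion_probes(
    config: FusionSimulationConfig | None = None,
    panel: FusionProbePanel | None = None,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a fusion-probe count matrix plus its truth record.

    Negative samples share one mean across 5' and 3' probes, with junction
    probes at background.  A positive sample has its target gene's 3' probes
    scaled by ``three_prime_fold`` and the true variant's junction probe
    drawn at ``junction_mean_on``; MET-skip positives suppress the exon-14
    probe and light the exon 13-15 junction.  Truth rows: sample_id, gene,
    variant (empty gene for negatives).
    """
    config = config or FusionSimulationConfig()
    panel = panel or default_fusion_panel()
    rng = np.random.default_rng(config.seed)

    variant_gene: dict[str, str] = {}
    for g, entry in panel.genes.items():
        for v in entry.variant_junction_probes:
            variant_gene[v] = g
    if panel.met is not None:
        variant_gene["MET_exon14"] = "MET"
    for v in config.positives_per_variant:
        if v not in variant_gene:
            raise ValueError(f"variant {v!r} not in probe panel")

    sample_ids = [f"F_{i:04d}" for i in range(config.n_samples)]
    assignment: dict[str, tuple[str, str]] = {}  # sample -> (gene, variant)
    i = 0
    for variant, count in config.positives_per_variant.items():
        for _ in range(count):
            assignment[sample_ids[i]] = (variant_gene[variant], variant)
            i += 1

    probe_ids: list[str] = []
    for entry in panel.genes.values():
        probe_ids += list(entry.five_prime_probes) + list(entry.three_prime_probes)
        probe_ids += list(entry.variant_junction_probes.values())
    if panel.met is not None:
        m = panel.met
        probe_ids += list(m.exons_3_4) + [m.exon_14] + list(m.exons_20_21) + [m.skip_junction_probe]
    probe_ids += list(panel.positive_control_ids)

    df = pd.DataFrame(0.0, index=probe_ids, columns=sample_ids)
    for sid in sample_ids:
        gene_pos, variant_pos = assignment.get(sid, ("", ""))
        for g, entry in panel.genes.items():
            fused = g == gene_pos
            for p in entry.five_prime_probes:
                df.loc[p, sid] = _nb_counts(rng, config.baseline_probe_mean, config.dispersion, 1)[0]
            mean3 = config.baseline_probe_mean * (config.three_prime_fold if fused else 1.0)
            disp3 = config.signal_dispersion if fused else config.dispersion
            for p in entry.three_prime_probes:
                df.loc[p, sid] = _nb_counts(rng, mean3, disp3, 1)[0]
            for v, p in entry.variant_junction_probes.items():
                if fused and v == variant_pos:
                    df.loc[p, sid] = _nb_counts(rng, config.junction_mean_on, config.signal_dispersion, 1)[0]
                else:
                    df.loc[p, sid] = _nb_counts(rng, config.junction_background_mean, config.dispersion, 1)[0]
        if panel.met is not None:
            m = panel.met
            skipped = variant_pos == "MET_exon14"
            for p in list(m.exons_3_4) + list(m.exons_20_21):
                df.loc[p, sid] = _nb_counts(rng, config.baseline_probe_mean, config.signal_dispersion, 1)[0]
            mean14 = config.baseline_probe_mean * (config.exon14_suppression if skipped else 1.0)
            df.loc[m.exon_14, sid] = _nb_counts(rng, mean14, config.dispersion, 1)[0]
            if skipped:
                df.loc[m.skip_junction_probe, sid] = _nb_counts(
                    rng, config.junction_mean_on, config.signal_dispersion, 1)[0]
            else:
                df.loc[m.skip_junction_probe, sid] = _nb_counts(
                    rng, config.junction_background_mean, config.dispersion, 1)[0]
        for p in panel.positive_control_ids:
            df.loc[p, sid] = _nb_counts(rng, config.positive_control_mean, config.signal_dispersion, 1)[0]

    # floor at 1 so ratio denominators are defined without background correction
    matrix = ExpressionMatrix(df.clip(lower=1.0), Platform.nanostring_counts)
    truth = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "gene": [assignment.get(s, ("", ""))[0] for s in sample_ids],
            "variant": [assignment.get(s, ("", ""))[1] for s in sample_ids],
        }
    )
    return matrix, truth


def platform_transform(
    matrix: ExpressionMatrix,
    mode: str,
    seed: int = 0,
    power: float = 2.0,
    slope: float = 3.0,
    offset: float = 5.0,
    factors: np.ndarray | None = None,
) -> ExpressionMatrix:
    """Emulate a platform change.

    ``log_shift``, ``power`` and ``affine_positive`` apply strictly
    increasing per-sample maps, under which rank-based predictions must not
    change.  ``gene_scale`` multiplies each gene by a random positive factor
    — NOT rank-preserving within a sample — probing the failure mode of
    per-gene rescaled data.
    """
    vals = matrix.values
    if mode == "log_shift":
        out = np.log1p(vals)
    elif mode == "power":
        if power <= 0:
            raise ValueError("power must be positive")
        out = vals ** power
    elif mode == "affine_positive":
        if slope <= 0:
            raise ValueError("affine slope must be positive")
        if offset < 0:
            raise ValueError("affine offset must be non-negative")
        out = slope * vals + offset
    elif mode == "gene_scale":
        if factors is None:
            rng = np.random.default_rng(seed)
            factors = rng.uniform(0.1, 10.0, size=vals.shape[0])
        factors = np.asarray(factors, dtype=float)
        if (factors <= 0).any():
            raise ValueError("gene_scale factors must be positive")
        out = vals.mul(factors, axis=0)
    else:
        raise ValueError(f"unknown transform mode {mode!r}")
    return ExpressionMatrix(out, Platform.unknown)
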