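"""Rank-based single-sample predictor (SSP) of NSCLC histology.

The classifier follows the AIMS construction: expression of a small marker
panel is reduced, within each sample independently, to binary gene-pair
rules ("expression(A) < expression(B)"), and a naive Bayes model over those
rules yields per-class posteriors.  Because each rule compares two genes
inside the same sample, the prediction is invariant to any strictly
increasing per-sample transform of the values — the property that makes the
predictor portable across NanoString counts, RNAseq FPKM and microarray
intensities without normalization.

The default marker panel is the 11-gene diagnostic set used for NSCLC
histology: CHGA/SYP/CD56 (LCNEC, neuroendocrine lineage), SFTPG/NAPSA/TTF-1
(adenocarcinoma) and TP73L/KRT6A/KRT5/KRT40/KRT16 (squamous lineage).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from sklearn.model_selection import StratifiedKFold

from .io_formats import ExpressionMatrix, Platform


class PairRule(NamedTuple):
    """Fires (value 1) for a sample iff expression(gene_low) < expression(gene_high), strict."""

    gene_low: str
    gene_high: str


@dataclass(frozen=True)
class MarkerPanel:
    """Histology classes mapped to their prototypic marker genes.

    ``alias_map`` maps a panel symbol to accepted synonyms so that matrices
    using a different symbol dialect (e.g. NKX2-1 for TTF-1) still resolve.
    """

    classes: Mapping[str, tuple[str, ...]]
    alias_map: Mapping[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for cls, genes in self.classes.items():
            for g in genes:
                if g in seen:
                    raise ValueError(f"gene {g!r} assigned to both {seen[g]!r} and {cls!r}")
                seen[g] = cls
        if len(seen) < 2:
            raise ValueError("marker panel needs at least two genes")
        # an alias may serve at most one panel gene
        owner: dict[str, str] = {}
        for g, aliases in self.alias_map.items():
            for a in aliases:
                if a in owner and owner[a] != g:
                    raise ValueError(f"alias {a!r} maps to both {owner[a]!r} and {g!r}")
                owner[a] = g

    @property
    def genes(self) -> tuple[str, ...]:
        """All panel genes, in class-then-gene declaration order."""
        return tuple(g for genes in self.classes.values() for g in genes)

    def accepted_names(self, gene: str) -> tuple[str, ...]:
        return (gene,) + tuple(self.alias_map.get(gene, ()))


def default_marker_panel() -> MarkerPanel:
    """The 11-gene NSCLC histology panel with common symbol aliases."""
    return MarkerPanel(
        classes={
            "LCNEC": ("CHGA", "SYP", "CD56"),
            "AC": ("SFTPG", "NAPSA", "TTF-1"),
            "SqCC": ("TP73L", "KRT6A", "KRT5", "KRT40", "KRT16"),
        },
        alias_map={
            "CD56": ("NCAM1",),
            "TTF-1": ("NKX2-1", "TTF1", "TITF1"),
            "TP73L": ("TP63", "p63"),
            "SFTPG": ("SFTA2",),
        },
    )


def load_marker_panel(path) -> MarkerPanel:
    """Load a marker panel from a YAML/JSON mapping with keys ``classes`` and ``aliases``."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    classes = {str(c): tuple(map(str, genes)) for c, genes in raw["classes"].items()}
    aliases = {str(g): tuple(map(str, a)) for g, a in raw.get("aliases", {}).items()}
    return MarkerPanel(classes=classes, alias_map=aliases)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def background_correct(
    matrix: ExpressionMatrix,
    negative_probe_ids: Sequence[str],
    floor: float = 1.0,
) -> ExpressionMatrix:
    """Subtract per-sample negative-control background from NanoString counts.

    Per sample the background is ``mean(negatives) + 2 * SD(negatives)``
    (sample SD); every endogenous value becomes ``max(value - background,
    floor)`` and the negative probes are dropped from the output.  The floor
    keeps downstream ratios well defined.
    """
    if floor <= 0:
        raise ValueError("floor must be positive")
    neg = [p for p in negative_probe_ids if p in matrix.values.index]
    if not neg:
        raise ValueError("no negative-control probes found in matrix; cannot background-correct")
    negs = matrix.values.loc[neg]
    sd = negs.std(axis=0, ddof=1).fillna(0.0) if len(neg) > 1 else pd.Series(0.0, index=matrix.values.columns)
    background = negs.mean(axis=0) + 2.0 * sd
    endo = matrix.values.drop(index=neg)
    corrected = (endo - background).clip(lower=floor)
    return ExpressionMatrix(corrected, matrix.platform)


def resolve_panel(matrix: ExpressionMatrix, panel: MarkerPanel) -> ExpressionMatrix:
    """Restrict a matrix to the panel genes (in panel order), resolving aliases.

    Each panel gene must match exactly one matrix row, either by its own
    symbol or one of its aliases; the output row is renamed to the panel
    symbol.  Missing genes and ambiguous matches are hard errors.
    """
    index = {str(g): str(g) for g in matrix.values.index}
    rows: list[str] = []
    missing: list[str] = []
    for gene in panel.genes:
        hits = [name for name in panel.accepted_names(gene) if name in index]
        if not hits:
            missing.append(f"{gene} (tried: {', '.join(panel.accepted_names(gene))})")
        elif len(hits) > 1:
            raise ValueError(
                f"ambiguous resolution for panel gene {gene!r}: matrix contains {hits}"
            )
        else:
            rows.append(hits[0])
    if missing:
        raise ValueError("panel genes not found in matrix: " + "; ".join(missing))
    sub = matrix.values.loc[rows].copy()
    sub.index = list(panel.genes)
    return ExpressionMatrix(sub, matrix.platform)


# ---------------------------------------------------------------------------
# Rule space
# ---------------------------------------------------------------------------

def enumerate_pair_rules(panel: MarkerPanel) -> list[PairRule]:
    """All ordered gene pairs over the panel: n*(n-1) candidate rules.

    Deterministic order: gene_low walks the panel first, so the 11-gene
    default yields 110 rules with both orientations of every pair present.
    """
    genes = panel.genes
    return [PairRule(a, b) for i, a in enumerate(genes) for j, b in enumerate(genes) if i != j]


def binarize_rules(panel_matrix: ExpressionMatrix, rules: Sequence[PairRule]) -> np.ndarray:
    """Evaluate pair rules per sample: 1 iff value(gene_low) < value(gene_high).

    Ties evaluate to 0 in both orientations — deterministic and safe for
    integer counts.  The output (rules x samples, uint8) depends only on the
    within-sample ranking, never on the scale.
    """
    vals = panel_matrix.values
    out = np.zeros((len(rules), vals.shape[1]), dtype=np.uint8)
    for i, rule in enumerate(rules):
        if rule.gene_low not in vals.index or rule.gene_high not in vals.index:
            raise ValueError(f"rule gene missing from matrix: {rule}")
        out[i] = (
            vals.loc[rule.gene_low].to_numpy() < vals.loc[rule.gene_high].to_numpy()
        ).astype(np.uint8)
    return out


def rank_rules(
    binary: np.ndarray,
    labels: Sequence[str],
    rules: Sequence[PairRule],
) -> dict[str, list[int]]:
    """Rank candidate rules per class by discrimination.

    Score of rule r for class c is ``|freq(r=1 | c) - freq(r=1 | not c)|``;
    higher is better, ties broken by enumeration order.  Within one class's
    list the reverse orientation of an already-ranked pair is skipped, so the
    list never spends two slots on the same gene pair.
    """
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    if len(classes) < 2:
        raise ValueError("need at least two classes to rank rules")
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
    ranked: dict[str, list[int]] = {}
    for c in classes:
        in_c = labels == c
        score = np.abs(binary[:, in_c].mean(axis=1) - binary[:, ~in_c].mean(axis=1))
        order = np.argsort(-score, kind="stable")
        picked: list[int] = []
        seen_pairs: set[frozenset[str]] = set()
        for idx in order:
            pair = frozenset(rules[idx])
            if pair in seen_pairs:
                continue
            seen_pairs.add(pair)
            picked.append(int(idx))
        ranked[c] = picked
    return ranked


def select_rules(
    ranked: Mapping[str, list[int]],
    k: int,
    rules: Sequence[PairRule],
) -> list[int]:
    """Round-robin top rules per class (by rank) until k distinct rules are selected.

    Classes are visited in sorted order; a pair already selected in either
    orientation is skipped, so the model never holds both orientations.
    """
    classes = sorted(ranked)
    selected: list[int] = []
    chosen_pairs: set[frozenset[str]] = set()
    depth = 0
    max_depth = max(len(v) for v in ranked.values())
    while len(selected) < k and depth < max_depth:
        for c in classes:
            if len(selected) >= k:
                break
            lst = ranked[c]
            if depth < len(lst):
                idx = lst[depth]
                pair = frozenset(rules[idx])
                if pair not in chosen_pairs:
                    chosen_pairs.add(pair)
                    selected.append(idx)
        depth += 1
    if len(selected) < k:
        raise ValueError(f"cannot select {k} distinct rules from the candidate set")
    return selected


# ---------------------------------------------------------------------------
# Naive Bayes over binary rules
# ---------------------------------------------------------------------------

def fit_naive_bayes(
    binary: np.ndarray,
    labels: Sequence[str],
    alpha: float = 1.0,
    priors_mode: str = "uniform",
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Laplace-smoothed Bernoulli naive Bayes parameters.

    ``P(rule=1 | c) = (count(rule=1, c) + alpha) / (n_c + 2*alpha)``, which
    keeps every conditional strictly inside (0, 1).  Priors are uniform by
    default (the rules are meant to be prototypic, so cohort composition
    should not leak into the model) or empirical class frequencies.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    labels = np.asarray(labels)
    classes = sorted(set(labels))
    cond = np.empty((binary.shape[0], len(classes)))
    priors = np.empty(len(classes))
    for j, c in enumerate(classes):
        in_c = labels == c
        n_c = int(in_c.sum())
        if n_c == 0:
            raise ValueError(f"empty class {c!r}")
        cond[:, j] = (binary[:, in_c].sum(axis=1) + alpha) / (n_c + 2.0 * alpha)
        priors[j] = n_c
    if priors_mode == "uniform":
        priors = np.full(len(classes), 1.0 / len(classes))
    elif priors_mode == "empirical":
        priors = priors / priors.sum()
    else:
        raise ValueError(f"unknown priors_mode {priors_mode!r}")
    return cond, priors, classes


def _posteriors(binary: np.ndarray, cond: np.ndarray, priors: np.ndarray) -> np.ndarray:
    """Log-space NB posteriors, samples x classes, rows summing to 1."""
    logp = np.log(cond)          # rules x classes
    log1mp = np.log1p(-cond)
    x = binary.astype(float)     # rules x samples
    loglik = x.T @ logp + (1.0 - x).T @ log1mp + np.log(priors)
    loglik -= loglik.max(axis=1, keepdims=True)
    post = np.exp(loglik)
    return post / post.sum(axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# Model, training, prediction
# ---------------------------------------------------------------------------

@dataclass
class Prediction:
    sample_id: str
    predicted_class: str
    posterior: dict[str, float]


@dataclass
class SSPModel:
    """A trained single-sample predictor: ordered pair rules + NB parameters."""

    classes: tuple[str, ...]
    rules: tuple[PairRule, ...]
    cond_prob: np.ndarray        # rules x classes, strictly in (0, 1)
    priors: np.ndarray
    smoothing_alpha: float
    panel: MarkerPanel
    k_grid: tuple[int, ...] = ()
    cv_record: dict[int, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        self.cond_prob = np.asarray(self.cond_prob, dtype=float)
        self.priors = np.asarray(self.priors, dtype=float)
        if self.cond_prob.shape != (len(self.rules), len(self.classes)):
            raise ValueError("cond_prob shape must be (n_rules, n_classes)")
        if not ((self.cond_prob > 0) & (self.cond_prob < 1)).all():
            raise ValueError("conditional probabilities must lie strictly in (0, 1)")
        if not np.isclose(self.priors.sum(), 1.0):
            raise ValueError("priors must sum to 1")
        pairs = [frozenset(r) for r in self.rules]
        if len(set(pairs)) != len(pairs):
            raise ValueError("a gene pair appears in both orientations (or twice)")

    @property
    def n_rules(self) -> int:
        return len(self.rules)

    def to_dict(self) -> dict:
        return {
            "classes": list(self.classes),
            "rules": [[r.gene_low, r.gene_high] for r in self.rules],
            "cond_prob": self.cond_prob.tolist(),
            "priors": self.priors.tolist(),
            "smoothing_alpha": self.smoothing_alpha,
            "panel": {
                "classes": {c: list(g) for c, g in self.panel.classes.items()},
                "aliases": {g: list(a) for g, a in self.panel.alias_map.items()},
            },
            "k_grid": list(self.k_grid),
            "cv_record": {str(k): v for k, v in self.cv_record.items()},
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SSPModel":
        required = {"classes", "rules", "cond_prob", "priors", "smoothing_alpha", "panel"}
        missing = required - set(d)
        if missing:
            raise ValueError(f"model payload missing fields: {sorted(missing)}")
        panel = MarkerPanel(
            classes={c: tuple(g) for c, g in d["panel"]["classes"].items()},
            alias_map={g: tuple(a) for g, a in d["panel"].get("aliases", {}).items()},
        )
        return cls(
            classes=tuple(d["classes"]),
            rules=tuple(PairRule(*r) for r in d["rules"]),
            cond_prob=np.array(d["cond_prob"], dtype=float),
            priors=np.array(d["priors"], dtype=float),
            smoothing_alpha=float(d["smoothing_alpha"]),
            panel=panel,
            k_grid=tuple(int(k) for k in d.get("k_grid", [])),
            cv_record={int(k): float(v) for k, v in d.get("cv_record", {}).items()},
            seed=int(d.get("seed", 0)),
        )


@dataclass
class TrainConfig:
    """Training hyper-parameters; the defaults realize a 5-fold CV over k = 1..25."""

    alpha: float = 1.0
    k_grid: tuple[int, ...] = tuple(range(1, 26))
    folds: int = 5
    seed: int = 0
    priors_mode: str = "uniform"


def _balanced_accuracy(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    classes = sorted(set(y_true))
    recalls = [np.mean(y_pred[y_true == c] == c) for c in classes]
    return float(np.mean(recalls))


def choose_rule_count(
    panel_matrix: ExpressionMatrix,
    labels: pd.Series,
    rules: Sequence[PairRule],
    k_grid: Sequence[int],
    folds: int = 5,
    seed: int = 0,
    alpha: float = 1.0,
    priors_mode: str = "uniform",
) -> tuple[int, dict[int, float]]:
    """Pick the rule count k by stratified cross-validated balanced accuracy.

    For each k, rules are re-ranked on each training fold, the top k chosen
    round-robin across classes, an NB fit, and held-out balanced accuracy
    recorded; k* is the smallest k achieving the maximum mean.  Deterministic
    given the seed.  Folds are reduced (with a warning) if the smallest class
    cannot support the requested stratification.
    """
    k_grid = sorted(set(int(k) for k in k_grid))
    y = labels.loc[panel_matrix.sample_ids].to_numpy()
    binary_all = binarize_rules(panel_matrix, rules)
    min_class = min(np.sum(y == c) for c in set(y))
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min_class < folds:
        warnings.warn(
            f"smallest class has {min_class} samples; reducing folds from {folds} to {min_class}"
        )
        folds = int(min_class)
    if max(k_grid) > len(rules):
        raise ValueError(f"k_grid max {max(k_grid)} exceeds candidate rule count {len(rules)}")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    per_k: dict[int, list[float]] = {k: [] for k in k_grid}
    for train_idx, val_idx in skf.split(np.zeros(len(y)), y):
        ranked = rank_rules(binary_all[:, train_idx], y[train_idx], rules)
        for k in k_grid:
            sel = select_rules(ranked, k, rules)
            cond, priors, classes = fit_naive_bayes(
                binary_all[np.ix_(sel, train_idx)], y[train_idx], alpha, priors_mode
            )
            post = _posteriors(binary_all[np.ix_(sel, val_idx)], cond, priors)
            pred = np.array(classes)[post.argmax(axis=1)]
            per_k[k].append(_balanced_accuracy(y[val_idx], pred))
    cv_record = {k: float(np.mean(v)) for k, v in per_k.items()}
    best = max(cv_record.values())
    k_star = min(k for k, v in cv_record.items() if v == best)
    return k_star, cv_record


def train_ssp(
    matrix: ExpressionMatrix,
    labels: pd.Series,
    panel: MarkerPanel | None = None,
    config: TrainConfig | None = None,
) -> SSPModel:
    """Train the single-sample histology predictor.

    Pipeline: restrict to the marker panel, binarize all ordered pair rules,
    select the rule count by stratified CV, then fit the final naive Bayes on
    the full cohort with the top k* rules.  Requires >= 3 samples per class.
    """
    panel = panel or default_marker_panel()
    config = config or TrainConfig()
    common = [s for s in matrix.sample_ids if s in labels.index]
    if not common:
        raise ValueError("no overlap between matrix samples and labels")
    matrix = matrix.subset_samples(common)
    y = labels.loc[common].astype(str)
    counts = y.value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"classes with fewer than 3 samples: {dict(small)}")
    panel_matrix = resolve_panel(matrix, panel)
    rules = enumerate_pair_rules(panel)
    k_star, cv_record = choose_rule_count(
        panel_matrix, y, rules, config.k_grid, config.folds, config.seed,
        config.alpha, config.priors_mode,
    )
    binary = binarize_rules(panel_matrix, rules)
    ranked = rank_rules(binary, y.to_numpy(), rules)
    sel = select_rules(ranked, k_star, rules)
    cond, priors, classes = fit_naive_bayes(
        binary[sel], y.to_numpy(), config.alpha, config.priors_mode
    )
    return SSPModel(
        classes=tuple(classes),
        rules=tuple(rules[i] for i in sel),
        cond_prob=cond,
        priors=priors,
        smoothing_alpha=config.alpha,
        panel=panel,
        k_grid=tuple(config.k_grid),
        cv_record=cv_record,
        seed=config.seed,
    )


def predict_ssp(model: SSPModel, matrix: ExpressionMatrix) -> list[Prediction]:
    """Classify each sample independently of all others.

    Posteriors come from the log-space naive Bayes over the model's binary
    rules; deleting or permuting other columns can never change a sample's
    result, and any strictly increasing per-sample transform of the values
    leaves predictions unchanged.  Argmax ties break to the first class in
    the model's (alphabetical) class order.
    """
    panel_matrix = resolve_panel(matrix, model.panel)
    binary = binarize_rules(panel_matrix, model.rules)
    post = _posteriors(binary, model.cond_prob, model.priors)
    out = []
    for i, sid in enumerate(panel_matrix.sample_ids):
        j = int(post[i].argmax())
        out.append(
            Prediction(
                sample_id=sid,
                predicted_class=model.classes[j],
                posterior={c: float(p) for c, p in zip(model.classes, post[i])},
            )
        )
    return out
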