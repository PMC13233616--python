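"""Ensemble species-distribution post-processing.

The statistical base learners are pluggable (registered by name); the
module's own substance is everything around them: collinearity screening
of predictors, pseudo-absence sampling, stratified splits, TSS/AUC
evaluation, TSS-weighted ensembling of passing models, max-TSS
binarization, stacked richness, and current-vs-future change assessment.
A deterministic percentile-envelope learner ships as the reference
implementation of the learner interface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .diversity import MetricSurface

# ---------------------------------------------------------------------------
# Predictor screening
# ---------------------------------------------------------------------------


def screen_predictors(
    samples: pd.DataFrame, r_max: float = 0.85
) -> tuple[list[str], list[str]]:
    """Iteratively drop predictors until all pairwise |Pearson r| <= r_max.

    While any pair exceeds the bound, the member of the worst pair with the
    larger mean absolute correlation to all other retained predictors is
    dropped (ties by name order).  Constant predictors are dropped first.
    Returns (retained, dropped) name lists.
    """
    if samples.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if samples.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    dropped: list[str] = []
    cols = list(samples.columns)
    for c in list(cols):
        if samples[c].std() == 0:
            cols.remove(c)
            dropped.append(c)
    while len(cols) > 1:
        corr = samples[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        worst = corr.values.max()
        if worst <= r_max:
            break
        i, j = np.unravel_index(np.argmax(corr.values), corr.shape)
        a, b = cols[i], cols[j]
        mean_a = corr.loc[a].mean()
        mean_b = corr.loc[b].mean()
        if mean_a > mean_b:
            victim = a
        elif mean_b > mean_a:
            victim = b
        else:
            victim = max(a, b)  # name-order tie break
        cols.remove(victim)
        dropped.append(victim)
    return cols, dropped


# ---------------------------------------------------------------------------
# Sampling and splitting
# ---------------------------------------------------------------------------


def sample_pseudo_absences(
    domain_cells: np.ndarray,
    n: int,
    exclusion: set[int] | np.ndarray,
    n_sets: int = 2,
    seed: int = 0,
) -> list[np.ndarray]:
    """``n_sets`` independent uniform samples (without replacement) of
    ``n`` cells from the domain minus the exclusion set."""
    domain_cells = np.asarray(domain_cells)
    excl = set(int(c) for c in np.atleast_1d(np.asarray(list(exclusion))))
    available = np.array([c for c in domain_cells if int(c) not in excl])
    if len(available) < n:
        raise ValueError(
            f"cannot sample {n} pseudo-absences from {len(available)} available cells"
        )
    master = np.random.default_rng(seed)
    sets = []
    for sub in master.spawn(n_sets):
        sets.append(np.sort(sub.choice(available, size=n, replace=False)))
    return sets


def split_train_test(
    points: pd.DataFrame,
    train_fraction: float = 0.7,
    seed: int = 0,
    label_col: str = "label",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified split: floor(f * n) of each label class to train."""
    if not 0 < train_fraction < 1:
        raise ValueError("train fraction must lie in (0, 1)")
    labels = points[label_col].unique()
    for lab in labels:
        if (points[label_col] == lab).sum() < 2:
            raise ValueError(f"label {lab!r} has fewer than 2 points")
    rng = np.random.default_rng(seed)
    train_idx = []
    for lab in sorted(labels):
        idx = points.index[points[label_col] == lab].to_numpy()
        k = int(np.floor(train_fraction * len(idx)))
        chosen = rng.choice(idx, size=k, replace=False)
        train_idx.extend(chosen.tolist())
    train_mask = points.index.isin(train_idx)
    return points.loc[train_mask], points.loc[~train_mask]


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------


@dataclass
class EvalStats:
    sensitivity: float
    specificity: float
    tss: float
    auc: float
    tss_max_threshold: float

    def passes(self, tss_min: float = 0.5, auc_min: float = 0.7) -> bool:
        return self.tss >= tss_min and self.auc >= auc_min


def stats_from_confusion(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, TSS) from confusion counts at a fixed
    operating point."""
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be represented")
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    return sens, spec, sens + spec - 1.0


def evaluate_predictions(scores, labels) -> EvalStats:
    """TSS/AUC evaluation of suitability scores against 0/1 labels.

    AUC uses the Mann-Whitney rank statistic with midranks for ties.  The
    threshold grid is the set of unique score values (prediction rule:
    presence iff score >= threshold); the reported operating point is the
    smallest threshold attaining the maximum TSS.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both presence and absence labels are required")

    ranks = rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0)

    pos = np.sort(scores[labels == 1])
    neg = np.sort(scores[labels == 0])
    thresholds = np.unique(scores)
    # counts of scores >= t via searchsorted on the sorted class arrays
    tp = n1 - np.searchsorted(pos, thresholds, side="left")
    fp = n0 - np.searchsorted(neg, thresholds, side="left")
    sens = tp / n1
    spec = (n0 - fp) / n0
    tss = sens + spec - 1.0
    best = np.max(tss)
    k = int(np.flatnonzero(tss == best)[0])  # thresholds ascending -> smallest
    return EvalStats(
        sensitivity=float(sens[k]),
        specificity=float(spec[k]),
        tss=float(best),
        auc=float(auc),
        tss_max_threshold=float(thresholds[k]),
    )


# ---------------------------------------------------------------------------
# Ensembling / binarization / stacking
# ---------------------------------------------------------------------------


class NoPassingModelError(RuntimeError):
    """No candidate model cleared the TSS/AUC retention bounds."""


def tss_weighted_ensemble(
    maps: list[np.ndarray],
    stats: list[EvalStats],
    tss_min: float = 0.5,
    auc_min: float = 0.7,
) -> tuple[np.ndarray, list[int]]:
    """TSS-weighted mean of the maps whose stats pass both bounds.

    Returns (ensemble map, indices of passing members).
    """
    if len(maps) != len(stats):
        raise ValueError("maps and stats differ in length")
    passing = [i for i, s in enumerate(stats) if s.passes(tss_min, auc_min)]
    if not passing:
        raise NoPassingModelError(
            f"none of {len(maps)} models reached TSS >= {tss_min} and AUC >= {auc_min}"
        )
    weights = np.array([stats[i].tss for i in passing], dtype=float)
    stack = np.vstack([np.asarray(maps[i], dtype=float) for i in passing])
    ens = weights @ stack / weights.sum()
    return ens, passing


def binarize(suitability: np.ndarray, threshold: float) -> np.ndarray:
    """Presence iff suitability >= threshold."""
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    return (np.asarray(suitability, dtype=float) >= threshold).astype(np.int8)


def stack_richness(
    binary_maps: dict[str, np.ndarray], cell_ids: np.ndarray, scenario: str = "current"
) -> MetricSurface:
    """Per-cell sum of per-species binary presence maps."""
    cell_ids = np.asarray(cell_ids)
    total = np.zeros(len(cell_ids), dtype=float)
    for sp, m in binary_maps.items():
        m = np.asarray(m)
        if m.shape != total.shape:
            raise ValueError(f"geometry mismatch for species {sp!r}")
        total += m
    return MetricSurface("SR_stacked", cell_ids, total, {"scenario": scenario})


# ---------------------------------------------------------------------------
# Change assessment
# ---------------------------------------------------------------------------


@dataclass
class ChangeAssessment:
    species: list[str]
    current_area: dict[str, int]
    future_area: dict[str, int]
    pct_change: dict[str, float]
    species_class: dict[str, str]  # increase | decrease | unchanged
    class_fractions: dict[str, float]
    delta_sr: np.ndarray
    cell_class: np.ndarray  # +1 / -1 / 0 per cell

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": self.species,
                "current_area": [self.current_area[s] for s in self.species],
                "future_area": [self.future_area[s] for s in self.species],
                "pct_change": [self.pct_change[s] for s in self.species],
                "class": [self.species_class[s] for s in self.species],
            }
        )


def change_assessment(
    current_maps: dict[str, np.ndarray],
    future_maps: dict[str, np.ndarray],
) -> ChangeAssessment:
    """Per-species range change and per-cell richness change between two
    scenarios.

    Percent change is (future - current) / current * 100.  A species with
    no current range is classed as an increase when it gains any future
    cell ('new range', percent change reported as inf), otherwise
    unchanged.
    """
    if set(current_maps) != set(future_maps):
        raise ValueError("species sets differ between scenarios")
    species = sorted(current_maps)
    cur_area, fut_area, pct, cls = {}, {}, {}, {}
    delta = None
    for sp in species:
        c = np.asarray(current_maps[sp])
        f = np.asarray(future_maps[sp])
        if c.shape != f.shape:
            raise ValueError(f"geometry mismatch for species {sp!r}")
        if delta is None:
            delta = np.zeros(c.shape, dtype=float)
        delta += f.astype(float) - c.astype(float)
        ca, fa = int(c.sum()), int(f.sum())
        cur_area[sp], fut_area[sp] = ca, fa
        if ca == 0:
            pct[sp] = float("inf") if fa > 0 else 0.0
            cls[sp] = "increase" if fa > 0 else "unchanged"
        else:
            pct[sp] = 100.0 * (fa - ca) / ca
            if fa > ca:
                cls[sp] = "increase"
            elif fa < ca:
                cls[sp] = "decrease"
            else:
                cls[sp] = "unchanged"
    n = len(species)
    fractions = {
        c: sum(1 for s in species if cls[s] == c) / n
        for c in ("increase", "decrease", "unchanged")
    }
    return ChangeAssessment(
        species=species,
        current_area=cur_area,
        future_area=fut_area,
        pct_change=pct,
        species_class=cls,
        class_fractions=fractions,
        delta_sr=delta,
        cell_class=np.sign(delta).astype(int),
    )


# ---------------------------------------------------------------------------
# Learner interface + reference envelope learner
# ---------------------------------------------------------------------------


class SuitabilityLearner:
    """Interface for pluggable base learners."""

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "SuitabilityLearner":
        raise NotImplementedError

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        raise NotImplementedError


@dataclass
class EnvelopeLearner(SuitabilityLearner):
    """Percentile-envelope reference learner.

    Suitability of a cell is the fraction of predictors whose value lies
    inside the [p, 100 - p] percentile window of the *presence* training
    values.  Deterministic; exists so the ensemble machinery is testable
    without external model packages.
    """

    percentile: float = 2.5
    _lo: pd.Series | None = field(default=None, repr=False)
    _hi: pd.Series | None = field(default=None, repr=False)

    def fit(self, X: pd.DataFrame, y: np.ndarray) -> "EnvelopeLearner":
        pres = X.loc[np.asarray(y) == 1]
        if len(pres) < 5:
            raise ValueError("need at least 5 training presences")
        self._lo = pres.quantile(self.percentile / 100.0)
        self._hi = pres.quantile(1.0 - self.percentile / 100.0)
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        if self._lo is None:
            raise RuntimeError("learner is not fitted")
        inside = (X.ge(self._lo, axis=1) & X.le(self._hi, axis=1)).to_numpy()
        return inside.mean(axis=1)


MODEL_REGISTRY: dict[str, type[SuitabilityLearner]] = {"envelope": EnvelopeLearner}


def get_learner(name: str, **kwargs) -> SuitabilityLearner:
    try:
        return MODEL_REGISTRY[name](**kwargs)
    except KeyError:
        raise KeyError(
            f"unknown learner {name!r}; registered: {sorted(MODEL_REGISTRY)}"
        ) from None


# ---------------------------------------------------------------------------
# Per-species pipeline
# ---------------------------------------------------------------------------


@dataclass
class SpeciesSDMResult:
    species: str
    ensemble: dict[str, np.ndarray]  # scenario -> suitability over domain cells
    binary: dict[str, np.ndarray]
    threshold: float
    member_stats: list[EvalStats]
    passing: list[int]


def run_species_sdm(
    species: str,
    presence_cells: np.ndarray,
    predictors: dict[str, pd.DataFrame],
    learner_names: list[str] | None = None,
    n_pseudo: int | None = None,
    n_sets: int = 2,
    n_runs: int = 10,
    train_fraction: float = 0.7,
    tss_min: float = 0.5,
    auc_min: float = 0.7,
    seed: int = 0,
    learner_kwargs: dict | None = None,
) -> SpeciesSDMResult:
    """Fit-evaluate-ensemble-binarize for one species.

    ``predictors`` maps scenario -> DataFrame indexed by domain cell id
    with one column per retained predictor; the 'current' scenario is
    required.  Each (pseudo-absence set x run) pair contributes one
    candidate model per learner; candidates passing the TSS/AUC bounds
    join the TSS-weighted ensemble.  The max-TSS threshold of the current
    ensemble, computed against all labeled points, binarizes every
    scenario.
    """
    if "current" not in predictors:
        raise ValueError("a 'current' predictor scenario is required")
    learner_names = learner_names or ["envelope"]
    learner_kwargs = learner_kwargs or {}
    cur = predictors["current"]
    domain = cur.index.to_numpy()
    presence_cells = np.asarray(presence_cells)
    if n_pseudo is None:
        n_pseudo = min(len(presence_cells) * 2, len(domain) - len(presence_cells))

    pa_sets = sample_pseudo_absences(
        domain, n_pseudo, set(int(c) for c in presence_cells), n_sets=n_sets, seed=seed
    )

    maps: list[np.ndarray] = []
    stats: list[EvalStats] = []
    run_rng = np.random.default_rng(seed).spawn(n_sets * n_runs)
    for si, pa in enumerate(pa_sets):
        pts = pd.DataFrame(
            {
                "cell": np.concatenate([presence_cells, pa]),
                "label": np.concatenate(
                    [np.ones(len(presence_cells), int), np.zeros(len(pa), int)]
                ),
            }
        )
        for run in range(n_runs):
            sub_seed = int(run_rng[si * n_runs + run].integers(2**31 - 1))
            train, test = split_train_test(pts, train_fraction, seed=sub_seed)
            Xtr = cur.loc[train["cell"].to_numpy()]
            Xte = cur.loc[test["cell"].to_numpy()]
            for lname in learner_names:
                learner = get_learner(lname, **learner_kwargs.get(lname, {}))
                learner.fit(Xtr, train["label"].to_numpy())
                test_scores = learner.predict(Xte)
                stats.append(evaluate_predictions(test_scores, test["label"].to_numpy()))
                maps.append(
                    {sc: learner.predict(predictors[sc]) for sc in predictors}
                )

    current_maps = [m["current"] for m in maps]
    ens_cur, passing = tss_weighted_ensemble(current_maps, stats, tss_min, auc_min)

    ensemble = {"current": ens_cur}
    weights = np.array([stats[i].tss for i in passing])
    for sc in predictors:
        if sc == "current":
            continue
        stack = np.vstack([maps[i][sc] for i in passing])
        ensemble[sc] = weights @ stack / weights.sum()

    # max-TSS operating point of the current ensemble over all labeled points
    all_cells = np.concatenate([presence_cells] + list(pa_sets))
    all_labels = np.concatenate(
        [np.ones(len(presence_cells), int)]
        + [np.zeros(len(pa), int) for pa in pa_sets]
    )
    pos = {int(c): i for i, c in enumerate(domain)}
    ens_scores = ens_cur[[pos[int(c)] for c in all_cells]]
    op = evaluate_predictions(ens_scores, all_labels)
    thr = op.tss_max_threshold

    binary = {sc: binarize(m, min(max(thr, 0.0), 1.0)) for sc, m in ensemble.items()}
    return SpeciesSDMResult(
        species=species,
        ensemble=ensemble,
        binary=binary,
        threshold=float(thr),
        member_stats=stats,
        passing=passing,
    )
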