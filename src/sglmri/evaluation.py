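"""Nested cross-validated model selection and performance criteria.

Model selection follows a nested 10-fold scheme: the cohort is split into
10 stratified outer folds; for each outer fold, the training portion is
split again into 10 stratified inner folds over which every candidate
penalty is scored by the mean log likelihood of the held-out inner
subjects,

    mu_logL = (1/n) sum_i log P(y_i | x_i; w),

the penalty maximizing mu_logL is selected, the model is refit on the full
outer-training set, and the outer test fold is scored.  The whole
procedure is repeated with re-shuffled folds, and metrics are reported as
mean +/- SD over repeats.

Performance criteria are the usual confusion-matrix rates (sensitivity,
specificity, accuracy, precision, recall, Fscore) plus the normalized
discriminative score: the log odds x'w of each test subject divided by the
maximum |x'w| over all pooled test predictions, so scores lie in [-1, 1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PenaltyConfig, SparseGroupLogit

#: probabilities are clipped here before taking logs, so a separable fit
#: cannot produce -inf log likelihoods
PROB_FLOOR = 1e-12


# ---------------------------------------------------------------------------
# Lambda grids
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LambdaGrid:
    """A named list of candidate penalties for one algorithm."""

    algorithm: str  # sLASSO | gLASSO | sgLASSO
    values: tuple[PenaltyConfig, ...]

    def __post_init__(self) -> None:
        for p in self.values:
            if self.algorithm == "sLASSO" and p.lambda_g != 0:
                raise ValueError("sLASSO grid entries must have lambda_g = 0")
            if self.algorithm == "gLASSO" and p.lambda_s != 0:
                raise ValueError("gLASSO grid entries must have lambda_s = 0")


def _logspace(lo: float, hi: float, num: int) -> np.ndarray:
    return np.logspace(np.log10(lo), np.log10(hi), num)


def lambda_grid(algorithm: str, preset: str = "full") -> LambdaGrid:
    """Full published-scale ("full") or reduced ("demo") penalty grids.

    Full-scale grids: sLASSO 200 log-spaced lambda_S in [0.01, 0.2512];
    gLASSO 100 log-spaced lambda_G in [0.1, 0.6310]; sgLASSO all 200
    combinations of 20 lambda_S in [1e-6, 0.1] with 10 lambda_G in
    [0.0631, 0.3162].  Demo grids keep the same ranges with 20 / 20 /
    10x2 points for fast runs.
    """
    if algorithm == "sLASSO":
        n = 200 if preset == "full" else 20
        vals = tuple(PenaltyConfig(ls, 0.0) for ls in _logspace(0.01, 0.2512, n))
    elif algorithm == "gLASSO":
        n = 100 if preset == "full" else 20
        vals = tuple(PenaltyConfig(0.0, lg) for lg in _logspace(0.1, 0.6310, n))
    elif algorithm == "sgLASSO":
        ns, ng = (20, 10) if preset == "full" else (10, 2)
        vals = tuple(
            PenaltyConfig(ls, lg)
            for ls in _logspace(1e-6, 0.1, ns)
            for lg in _logspace(0.0631, 0.3162, ng)
        )
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    return LambdaGrid(algorithm, vals)


# ---------------------------------------------------------------------------
# Performance criteria
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConfusionCounts:
    """tp/fn: patients correctly/incorrectly classified; tn/fp: controls."""

    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fn + other.fn, self.tn + other.tn, self.fp + other.fp
        )

    @classmethod
    def from_labels(cls, y_true, y_pred) -> "ConfusionCounts":
        y_true = np.asarray(y_true)
        y_pred = np.asarray(y_pred)
        return cls(
            tp=int(np.sum((y_true == 1) & (y_pred == 1))),
            fn=int(np.sum((y_true == 1) & (y_pred == -1))),
            tn=int(np.sum((y_true == -1) & (y_pred == -1))),
            fp=int(np.sum((y_true == -1) & (y_pred == 1))),
        )


def _ratio(num: int, den: int) -> float:
    """A rate, or NaN (reported as undefined, not 0) when the denominator is 0."""
    return num / den if den > 0 else float("nan")


def metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Sensitivity, specificity, accuracy, precision, recall, Fscore.

    Fscore = TP / (TP + (FN + FP)/2), the harmonic mean of precision and
    recall.  Undefined rates (zero denominator) come back as NaN.
    """
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    sens = _ratio(tp, tp + fn)
    spec = _ratio(tn, tn + fp)
    acc = _ratio(tp + tn, tp + fn + tn + fp)
    prec = _ratio(tp, tp + fp)
    fscore = tp / (tp + (fn + fp) / 2) if (2 * tp + fn + fp) > 0 else float("nan")
    return {
        "sensitivity": sens,
        "specificity": spec,
        "accuracy": acc,
        "precision": prec,
        "recall": sens,
        "fscore": fscore,
    }


def mean_loglik(prob_true: np.ndarray) -> float:
    """mu_logL: mean log probability assigned to the true labels (<= 0)."""
    p = np.clip(np.asarray(prob_true, dtype=float), PROB_FLOOR, 1.0)
    if p.size == 0:
        raise ValueError("empty probability vector")
    return float(np.mean(np.log(p)))


@dataclass
class ScoreSet:
    """Normalized discriminative scores of pooled test subjects.

    score_i = x_i'w / max_k |x_k'w| over the pooled test predictions, so
    all scores lie in [-1, 1] and at least one attains |score| = 1.
    """

    scores: np.ndarray
    predicted: np.ndarray
    true_labels: np.ndarray
    subject_ids: list


def discriminative_scores(log_odds, predicted, true_labels, subject_ids=None) -> ScoreSet:
    """Normalize pooled log odds by their maximum magnitude."""
    lo = np.asarray(log_odds, dtype=float)
    denom = np.max(np.abs(lo))
    scores = lo / denom if denom > 0 else lo.copy()
    if subject_ids is None:
        subject_ids = list(range(lo.size))
    return ScoreSet(scores, np.asarray(predicted), np.asarray(true_labels), list(subject_ids))


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def make_folds(labels, k: int = 10, rng=None) -> np.ndarray:
    """Stratified fold assignment: controls and patients split separately.

    Each class is shuffled and dealt into k folds whose per-class sizes
    differ by at most one.  Returns a length-n integer array of fold ids.
    Deterministic given the RNG/seed.
    """
    rng = np.random.default_rng(rng)
    labels = np.asarray(labels)
    fold = np.full(labels.shape[0], -1, dtype=int)
    for cls in (-1, 1):
        idx = np.flatnonzero(labels == cls)
        if idx.size == 0:
            continue
        if idx.size < k:
            raise ValueError(
                f"class {cls} has {idx.size} members, fewer than k={k}; use smaller k"
            )
        perm = rng.permutation(idx)
        fold[perm] = np.arange(perm.size) % k
    return fold


# ---------------------------------------------------------------------------
# Inner selection and nested CV
# ---------------------------------------------------------------------------

@dataclass
class InnerSelection:
    """Outcome of an inner CV penalty search (with audit trail)."""

    penalty: PenaltyConfig
    mu_logl: float
    table: pd.DataFrame  # per grid point: lambda_s, lambda_g, mu_logl
    train_indices: np.ndarray  # rows of the full data the search saw
    tie: bool = False
    n_excluded: int = 0


def _fit_grid_on(X, y, membership, grid: LambdaGrid, **fit_opts):
    model = SparseGroupLogit(y, X, groups=membership)
    return model.fit_path(list(grid.values), **fit_opts)


def inner_select(
    X, y, membership, grid: LambdaGrid, k: int = 10, rng=None,
    train_indices=None, **fit_opts
) -> InnerSelection:
    """Pick the penalty maximizing the pooled inner-CV mean log likelihood.

    For each grid point, all inner-test subjects are pooled and mu_logL is
    computed over the union (robust to unequal fold sizes).  Ties are
    broken toward the sparser model: larger lambda_s, then larger
    lambda_g; the tie is flagged.  Grid points whose fits diverge on any
    inner fold are excluded with a warning.
    """
    rng = np.random.default_rng(rng)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    folds = make_folds(y, k=k, rng=rng)
    n_grid = len(grid.values)
    logps: list[list[np.ndarray]] = [[] for _ in range(n_grid)]
    ok = np.ones(n_grid, dtype=bool)
    for f in range(k):
        tr = folds != f
        te = ~tr
        results = _fit_grid_on(X[tr], y[tr], membership, grid, **fit_opts)
        # fit_path returns results in its own (descending-penalty) order;
        # map them back to grid order
        by_pen = {r.penalty: r for r in results}
        for gi, pen in enumerate(grid.values):
            res = by_pen[pen]
            if not res.converged:
                ok[gi] = False
                continue
            margins = y[te] * res.linear_score(X[te])
            p_true = 1.0 / (1.0 + np.exp(-margins))
            logps[gi].append(np.clip(p_true, PROB_FLOOR, 1.0))
    rows = []
    for gi, pen in enumerate(grid.values):
        if not ok[gi]:
            continue
        mu = mean_loglik(np.concatenate(logps[gi]))
        rows.append({"lambda_s": pen.lambda_s, "lambda_g": pen.lambda_g, "mu_logl": mu})
    if not rows:
        raise RuntimeError("all grid points diverged in the inner CV")
    table = pd.DataFrame(rows)
    best_mu = table["mu_logl"].max()
    contenders = table[table["mu_logl"] == best_mu]
    tie = len(contenders) > 1
    pick = contenders.sort_values(["lambda_s", "lambda_g"], ascending=False).iloc[0]
    return InnerSelection(
        penalty=PenaltyConfig(pick["lambda_s"], pick["lambda_g"]),
        mu_logl=float(best_mu),
        table=table,
        train_indices=np.asarray(train_indices if train_indices is not None else np.arange(len(y))),
        tie=tie,
        n_excluded=int((~ok).sum()),
    )


@dataclass
class FoldRecord:
    """One outer fold of one repeat, with full provenance."""

    repeat: int
    fold: int
    train_indices: np.ndarray
    test_indices: np.ndarray
    penalty: PenaltyConfig
    inner: InnerSelection
    weights: np.ndarray
    converged: bool
    test_log_odds: np.ndarray
    test_prob_pos: np.ndarray
    test_predicted: np.ndarray
    test_true: np.ndarray


@dataclass
class CVReport:
    """All fold records plus aggregate metrics of a nested-CV run."""

    records: list[FoldRecord]
    per_repeat: pd.DataFrame  # one row per repeat: pooled-confusion metrics
    summary: pd.DataFrame  # mean and SD of each metric over repeats
    scores: ScoreSet  # pooled over every test prediction of the run
    n_repeats: int
    k: int
    seed: int
    algorithm: str

    def weight_matrix(self) -> np.ndarray:
        """(n_models, d) array of fitted weights, for stability analysis."""
        return np.vstack([r.weights for r in self.records])

    def per_repeat_tsv(self, path) -> None:
        self.per_repeat.to_csv(path, sep="\t", index=False)


def nested_cv(
    X, y, membership, grid: LambdaGrid,
    n_repeats: int = 100, k: int = 10, seed: int = 0, **fit_opts
) -> CVReport:
    """Nested stratified k-fold cross-validation with inner penalty search.

    Per repeat: subjects are dealt into k stratified outer folds; for each
    outer fold the remaining subjects form the outer-training set, an
    inner k-fold search over ``grid`` picks the penalty with maximal
    mu_logL, the model is refit on the outer-training set, and the test
    fold's probabilities are recorded.  Every subject is scored exactly
    once per repeat; inner folds never touch the outer test subjects.
    Repeats re-shuffle all folds; all RNG streams derive from ``seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n = y.shape[0]
    master = np.random.default_rng(seed)
    records: list[FoldRecord] = []
    repeat_rows = []
    for rep in range(n_repeats):
        rep_rng = np.random.default_rng(master.integers(2**31))
        outer = make_folds(y, k=k, rng=rep_rng)
        scored = np.zeros(n, dtype=int)
        rep_counts = ConfusionCounts(0, 0, 0, 0)
        rep_probs: list[np.ndarray] = []
        for f in range(k):
            te = np.flatnonzero(outer == f)
            tr = np.flatnonzero(outer != f)
            sel = inner_select(
                X[tr], y[tr], membership, grid, k=k, rng=rep_rng,
                train_indices=tr, **fit_opts
            )
            model = SparseGroupLogit(y[tr], X[tr], groups=membership)
            res = model.fit(sel.penalty, **fit_opts)
            log_odds = res.linear_score(X[te])
            prob_pos = res.predict_proba(X[te])
            pred = res.predict(X[te])
            records.append(
                FoldRecord(
                    repeat=rep, fold=f, train_indices=tr, test_indices=te,
                    penalty=sel.penalty, inner=sel, weights=res.params,
                    converged=res.converged, test_log_odds=log_odds,
                    test_prob_pos=prob_pos, test_predicted=pred, test_true=y[te],
                )
            )
            rep_counts = rep_counts + ConfusionCounts.from_labels(y[te], pred)
            margins = y[te] * log_odds
            rep_probs.append(1.0 / (1.0 + np.exp(-margins)))
            scored[te] += 1
        if not np.all(scored == 1):
            raise AssertionError("each subject must be scored exactly once per repeat")
        mu = mean_loglik(np.concatenate(rep_probs))
        row = {"repeat": rep, **metrics(rep_counts), "mu_logl": mu,
               "likelihood_exp": float(np.exp(mu)),
               "likelihood_meanp": float(np.mean(np.concatenate(rep_probs)))}
        repeat_rows.append(row)

    per_repeat = pd.DataFrame(repeat_rows)
    metric_cols = [c for c in per_repeat.columns if c != "repeat"]
    summary = pd.DataFrame(
        {"mean": per_repeat[metric_cols].mean(), "sd": per_repeat[metric_cols].std(ddof=1)}
    )
    pooled_lo = np.concatenate([r.test_log_odds for r in records])
    pooled_pred = np.concatenate([r.test_predicted for r in records])
    pooled_true = np.concatenate([r.test_true for r in records])
    scores = discriminative_scores(pooled_lo, pooled_pred, pooled_true)
    return CVReport(
        records=records, per_repeat=per_repeat, summary=summary, scores=scores,
        n_repeats=n_repeats, k=k, seed=seed, algorithm=grid.algorithm,
    )


def rank_sum_compare(metric_a, metric_b) -> float:
    """Two-sided Mann-Whitney u-test p-value between two metric samples.

    A convenience for comparing per-repeat metric distributions between
    algorithms (e.g. gLASSO vs sLASSO Fscores).
    """
    from scipy.stats import mannwhitneyu

    return float(mannwhitneyu(metric_a, metric_b, alternative="two-sided").pvalue)
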