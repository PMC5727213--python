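"""Stepwise discriminant function analysis for two-bulk marker screening.

Features are selected one at a time by the partial-Wilks criterion: with
``p`` variables already entered, a candidate's F-to-enter is

    F = ((n - g - p) / (g - 1)) * (lambda_p / lambda_{p+1} - 1)

on (g-1, n-g-p) degrees of freedom, where Wilks' lambda is
``det(W)/det(T)`` (within-group over total scatter).  The candidate with
the largest F enters when its p-value is at or below the entry threshold
(default 0.05); after each entry, entered variables whose F-to-remove
p-value reaches the removal threshold (default 0.10) are dropped.  Group
membership is then predicted with Fisher's linear classification functions

    score_k(x) = b_k' x + c_k,   b_k = Sw^{-1} m_k,
    c_k = -1/2 m_k' Sw^{-1} m_k + ln(prior_k)

with ``Sw = W/(n-g)`` the pooled within-group covariance.  Reported rates
are the original (resubstitution) percent correct, the leave-one-out
percent (classification functions refit per fold, feature set frozen) and,
for the replicate-split design, the held-out biological-replicate percent:
the six technical replicates of the first biological replicate of each bulk
train the model and the second biological replicate is the test set, after
which the selected features are re-run through stepwise on all 12 + 12
points to form the final classification model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bulks import BulkDesign
from .errors import CollinearityError, ConfigurationError, DegenerateInputError
from .signals import SignalMatrix


@dataclass(frozen=True)
class DfaConfig:
    """Stepwise selection thresholds (probability-of-F form)."""

    p_enter: float = 0.05
    p_remove: float = 0.10
    max_steps: int = 10
    prior: str = "equal"  # "equal" | "proportional"
    tolerance: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 < self.p_enter <= self.p_remove < 1):
            raise ConfigurationError(
                "require 0 < p_enter <= p_remove < 1 "
                f"(got {self.p_enter}, {self.p_remove})"
            )
        if self.prior not in ("equal", "proportional"):
            raise ConfigurationError(f"unknown prior {self.prior!r}")


@dataclass
class DfaModel:
    """Result of stepwise selection on one training matrix."""

    features: tuple[str, ...]
    lambda_trace: tuple[float, ...]  # lambda after each retained entry state
    n: int
    groups: tuple[str, ...]
    no_discriminators: bool = False
    config: DfaConfig = field(default_factory=DfaConfig)

    @property
    def g(self) -> int:
        return len(self.groups)


@dataclass
class ClassificationFunctions:
    """Fisher linear classification functions for each group."""

    groups: tuple[str, ...]
    features: tuple[str, ...]
    coef: pd.DataFrame  # features x groups
    const: pd.Series  # per group

    def scores(self, X: pd.DataFrame) -> pd.DataFrame:
        missing = set(self.features) - set(X.columns)
        if missing:
            raise KeyError(f"samples lack model features: {sorted(missing)}")
        vals = X[list(self.features)].to_numpy(dtype=float)
        s = vals @ self.coef.to_numpy(dtype=float) + self.const.to_numpy()
        return pd.DataFrame(s, index=X.index, columns=list(self.groups))

    def classify(self, X: pd.DataFrame) -> pd.Series:
        """Assign each sample to the group with the highest score.

        Exact ties break deterministically to the first group label.
        """
        s = self.scores(X)
        idx = s.to_numpy().argmax(axis=1)  # argmax takes first on ties
        return pd.Series([self.groups[i] for i in idx], index=X.index)


@dataclass
class ClassificationReport:
    """Percent-correct rates; every value is 100*k/n for integer k."""

    original_pct: float | None
    cross_validated_pct: float | None
    holdout_pct: float | None
    confusion: pd.DataFrame | None
    n_train: int
    n_test: int = 0


# ---------------------------------------------------------------------------
# Scatter matrices and Wilks' lambda
# ---------------------------------------------------------------------------

def _scatter(X: np.ndarray, y: np.ndarray, groups: Sequence) -> tuple[np.ndarray, np.ndarray]:
    """Within-group (W) and total (T) scatter matrices."""
    centred = X - X.mean(axis=0)
    T = centred.T @ centred
    W = np.zeros_like(T)
    for grp in groups:
        Xg = X[y == grp]
        cg = Xg - Xg.mean(axis=0)
        W += cg.T @ cg
    return W, T


def wilks_lambda(
    X: pd.DataFrame,
    y: pd.Series,
    features: Sequence[str],
) -> float:
    """Wilks' lambda det(W)/det(T) for the given feature subset.

    The empty set gives 1.  A singular total scatter (collinear or constant
    features) raises :class:`CollinearityError`; a singular within-group
    scatter with remaining between-group spread returns 0 (complete
    separation limit).
    """
    features = list(features)
    if not features:
        return 1.0
    groups = sorted(pd.unique(y))
    n, g = len(X), len(groups)
    if n <= g + len(features) - 1:
        raise DegenerateInputError(
            f"need n > g + p - 1 samples (n={n}, g={g}, p={len(features)})"
        )
    vals = X[features].to_numpy(dtype=float)
    W, T = _scatter(vals, y.to_numpy(), groups)
    sign_t, logdet_t = np.linalg.slogdet(T)
    if sign_t <= 0 or not np.isfinite(logdet_t):
        raise CollinearityError(
            f"singular total scatter for features {features}"
        )
    sign_w, logdet_w = np.linalg.slogdet(W)
    if sign_w <= 0 or not np.isfinite(logdet_w):
        return 0.0
    lam = float(np.exp(logdet_w - logdet_t))
    return min(lam, 1.0)


# ---------------------------------------------------------------------------
# Stepwise selection
# ---------------------------------------------------------------------------

def _partial_f(lam_old: float, lam_new: float, n: int, g: int, p: int) -> float:
    """F-to-enter going from p to p+1 variables (df (g-1, n-g-p))."""
    if lam_new <= 0:
        return np.inf
    return ((n - g - p) / (g - 1)) * (lam_old / lam_new - 1.0)


def _residual_ratio(S: np.ndarray, idx_e: list[int],
                    j: np.ndarray) -> np.ndarray:
    """Residual sums of squares S_jj - S_jE S_EE^-1 S_Ej for candidates j."""
    diag = S[j, j]
    if not idx_e:
        return diag
    S_ee = S[np.ix_(idx_e, idx_e)]
    S_ej = S[np.ix_(idx_e, j)]
    try:
        sol = np.linalg.solve(S_ee, S_ej)
    except np.linalg.LinAlgError:
        return np.full(len(j), np.nan)
    return diag - np.einsum("ij,ij->j", S_ej, sol)


def stepwise_select(
    X: pd.DataFrame,
    y: pd.Series,
    config: DfaConfig | None = None,
) -> DfaModel:
    """Stepwise Wilks'-lambda feature selection on samples x features data.

    Entry: the candidate with the largest F-to-enter joins the model when
    its p-value is at most ``p_enter`` (ties break to the lexicographically
    smallest feature id).  Removal: after each entry, the entered variable
    with the weakest F-to-remove leaves when its p-value is at least
    ``p_remove``.  Candidates whose within-group tolerance against entered
    variables falls below ``config.tolerance`` are skipped.  Returns an
    empty model flagged ``no_discriminators`` when nothing qualifies.

    The scan uses the residual-ratio identity: adding variable j changes
    Wilks' lambda by the factor ``w_res_j / t_res_j``, the within- over
    total-scatter residual sums of squares of j after sweeping out the
    entered variables.  This is algebraically identical to recomputing
    det(W)/det(T) per candidate, just vectorised.
    """
    config = config or DfaConfig()
    groups = tuple(sorted(pd.unique(y)))
    g = len(groups)
    n = len(X)
    if g < 2:
        raise DegenerateInputError("need at least 2 groups")
    counts = y.value_counts()
    if (counts < 2).any():
        raise DegenerateInputError("every group needs at least 2 samples")

    feats = list(X.columns)
    order = {f: i for i, f in enumerate(feats)}
    vals = X.to_numpy(dtype=float)
    W, T = _scatter(vals, y.to_numpy(), groups)

    entered: list[str] = []
    trace: list[float] = []
    lam_current = 1.0
    steps = 0
    while steps < config.max_steps:
        p = len(entered)
        if n - g - p < 1 or lam_current <= 0:
            break
        idx_e = [order[f] for f in entered]
        cand_names = sorted(f for f in feats if f not in entered)
        cand = np.array([order[f] for f in cand_names], dtype=int)
        if cand.size == 0:
            break
        w_res = _residual_ratio(W, idx_e, cand)
        t_res = _residual_ratio(T, idx_e, cand)
        diag_w = W[cand, cand]
        with np.errstate(divide="ignore", invalid="ignore"):
            tolerance = np.where(diag_w > 0, w_res / diag_w, 0.0)
            ratio = w_res / t_res
        ok = (
            np.isfinite(t_res) & (t_res > 0)
            & np.isfinite(tolerance) & (tolerance >= config.tolerance)
            & np.isfinite(ratio) & (ratio >= 0)
        )
        if not ok.any():
            break
        ratio = np.where(ok, np.clip(ratio, 0.0, 1.0), np.inf)
        with np.errstate(divide="ignore"):
            f_vals = ((n - g - p) / (g - 1)) * (1.0 / ratio - 1.0)
        # max F; exact ties break to the lexicographically smallest id
        best = int(np.lexsort((np.arange(cand.size), -f_vals))[0])
        best_f = float(f_vals[best])
        p_val = float(stats.f.sf(best_f, g - 1, n - g - p)) if np.isfinite(
            best_f) else 0.0
        if p_val > config.p_enter:
            break
        entered.append(cand_names[best])
        lam_current = lam_current * float(ratio[best])
        trace.append(lam_current)
        steps += 1
        if lam_current <= 0:
            break  # complete separation: nothing left to explain
        # --- removal scan (repeat until stable) ---
        while len(entered) > 1:
            p = len(entered)
            worst_feat, worst_f = None, np.inf
            for feat in entered:
                rest = [f for f in entered if f != feat]
                lam_rest = wilks_lambda(X, y, rest)
                f_rem = _partial_f(lam_rest, lam_current, n, g, p - 1)
                if f_rem < worst_f:
                    worst_feat, worst_f = feat, f_rem
            p_rem = float(stats.f.sf(worst_f, g - 1, n - g - p + 1))
            if p_rem < config.p_remove or worst_feat == entered[-1]:
                break
            entered.remove(worst_feat)
            lam_current = wilks_lambda(X, y, entered)
            trace.append(lam_current)
    return DfaModel(
        features=tuple(entered),
        lambda_trace=tuple(trace),
        n=n,
        groups=groups,
        no_discriminators=not entered,
        config=config,
    )


# ---------------------------------------------------------------------------
# Fisher classification functions
# ---------------------------------------------------------------------------

def fit_classifier(
    X: pd.DataFrame,
    y: pd.Series,
    features: Sequence[str],
    prior: str = "equal",
) -> ClassificationFunctions:
    """Fit Fisher's linear classification functions on the given features."""
    features = tuple(features)
    if not features:
        raise DegenerateInputError("cannot fit a classifier with no features")
    groups = tuple(sorted(pd.unique(y)))
    n, g = len(X), len(groups)
    vals = X[list(features)].to_numpy(dtype=float)
    W, _ = _scatter(vals, y.to_numpy(), groups)
    Sw = W / (n - g)
    try:
        Sw_inv = np.linalg.inv(Sw)
    except np.linalg.LinAlgError as exc:
        raise CollinearityError(
            f"singular pooled covariance for features {list(features)}"
        ) from exc
    coef = {}
    const = {}
    for grp in groups:
        m_k = vals[y.to_numpy() == grp].mean(axis=0)
        if prior == "equal":
            pk = 1.0 / g
        else:
            pk = float((y == grp).mean())
        b_k = Sw_inv @ m_k
        coef[grp] = b_k
        const[grp] = float(-0.5 * m_k @ Sw_inv @ m_k + np.log(pk))
    return ClassificationFunctions(
        groups=groups,
        features=features,
        coef=pd.DataFrame(coef, index=list(features)),
        const=pd.Series(const),
    )


def _pct(correct: int, n: int) -> float:
    return 100.0 * correct / n


def classify_and_report(
    model: DfaModel,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    X_test: pd.DataFrame | None = None,
    y_test: pd.Series | None = None,
) -> ClassificationReport:
    """Original, leave-one-out and (optional) holdout percent correct.

    Leave-one-out refits the classification functions for every fold with
    the feature set frozen to the model's selection.
    """
    if model.no_discriminators:
        return ClassificationReport(None, None, None, None,
                                    n_train=len(X_train),
                                    n_test=0 if X_test is None else len(X_test))
    funcs = fit_classifier(X_train, y_train, model.features,
                           prior=model.config.prior)
    pred = funcs.classify(X_train)
    original = _pct(int((pred == y_train).sum()), len(X_train))
    confusion = pd.crosstab(y_train, pred, rownames=["actual"],
                            colnames=["predicted"])
    # leave-one-out with refit classification functions
    correct = 0
    for idx in X_train.index:
        mask = X_train.index != idx
        fold = fit_classifier(X_train[mask], y_train[mask], model.features,
                              prior=model.config.prior)
        if fold.classify(X_train.loc[[idx]]).iloc[0] == y_train.loc[idx]:
            correct += 1
    loo = _pct(correct, len(X_train))
    holdout = None
    n_test = 0
    if X_test is not None and y_test is not None and len(X_test):
        pred_t = funcs.classify(X_test)
        holdout = _pct(int((pred_t == y_test).sum()), len(X_test))
        n_test = len(X_test)
    return ClassificationReport(original, loo, holdout, confusion,
                                n_train=len(X_train), n_test=n_test)


# ---------------------------------------------------------------------------
# Per-compound screening with the replicate-split design
# ---------------------------------------------------------------------------

def screen_compound(
    matrix: SignalMatrix,
    design: BulkDesign | None = None,
    config: DfaConfig | None = None,
) -> tuple[DfaModel, ClassificationReport]:
    """Run the full per-compound screen on one bulk-hybridisation matrix.

    Stepwise selection runs on the first biological replicate (6 + 6
    technical replicates); the fitted functions predict the second
    biological replicate (holdout).  The selected features are then put
    through stepwise again on all 12 + 12 data points and the final model's
    original and leave-one-out rates are reported alongside the holdout
    rate.  ``design`` is carried only as provenance of the bulk membership.
    """
    config = config or DfaConfig()
    X, labels, bio = matrix.to_wide()
    if set(pd.unique(labels)) != {"H", "L"}:
        raise DegenerateInputError("matrix must cover both H and L bulks")
    first_rep = bio == sorted(bio.unique())[0]
    X_train, y_train = X[first_rep], labels[first_rep]
    X_test, y_test = X[~first_rep], labels[~first_rep]

    round1 = stepwise_select(X_train, y_train, config)
    if round1.no_discriminators:
        report = ClassificationReport(None, None, None, None,
                                      n_train=len(X), n_test=0)
        return DfaModel((), (), len(X), round1.groups, True, config), report
    holdout_report = classify_and_report(round1, X_train, y_train,
                                         X_test, y_test)
    final = stepwise_select(X[list(round1.features)], labels, config)
    report = classify_and_report(final, X, labels)
    report.holdout_pct = holdout_report.holdout_pct
    report.n_test = holdout_report.n_test
    return final, report
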