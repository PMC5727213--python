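"""Independent re-implementations used as oracles by the test suite.

These deliberately use the naive definitions (explicit determinant ratios,
exhaustive candidate enumeration) rather than the package's vectorised
sweep, so they can certify the production code path.
"""

import numpy as np
import pandas as pd
from scipy import stats


def naive_wilks(X: pd.DataFrame, y: pd.Series, features) -> float:
    """det(W)/det(T) computed directly from the definition."""
    vals = X[list(features)].to_numpy(dtype=float)
    total = vals - vals.mean(axis=0)
    T = total.T @ total
    W = np.zeros_like(T)
    for grp in sorted(pd.unique(y)):
        sub = vals[(y == grp).to_numpy()]
        c = sub - sub.mean(axis=0)
        W += c.T @ c
    return float(np.linalg.det(W) / np.linalg.det(T))


def brute_stepwise(X: pd.DataFrame, y: pd.Series,
                   p_enter: float = 0.05, p_remove: float = 0.10,
                   max_steps: int = 10) -> tuple:
    """Exhaustive greedy stepwise selection (entry + removal)."""
    n, g = len(X), len(pd.unique(y))
    entered: list = []
    lam = 1.0
    while len(entered) < max_steps and n - g - len(entered) >= 1 and lam > 0:
        best = None
        for feat in sorted(c for c in X.columns if c not in entered):
            try:
                lam_new = naive_wilks(X, y, entered + [feat])
            except np.linalg.LinAlgError:
                continue
            if not np.isfinite(lam_new) or lam_new < 0:
                continue
            p = len(entered)
            f_val = (np.inf if lam_new == 0 else
                     ((n - g - p) / (g - 1)) * (lam / lam_new - 1.0))
            if best is None or f_val > best[1]:
                best = (feat, f_val, lam_new)
        if best is None:
            break
        p = len(entered)
        p_val = (0.0 if not np.isfinite(best[1])
                 else float(stats.f.sf(best[1], g - 1, n - g - p)))
        if p_val > p_enter:
            break
        entered.append(best[0])
        lam = best[2]
        while len(entered) > 1:
            worst = None
            for feat in entered:
                rest = [f for f in entered if f != feat]
                lam_rest = naive_wilks(X, y, rest)
                p = len(entered)
                f_rem = (np.inf if lam == 0 else
                         ((n - g - p + 1) / (g - 1)) * (lam_rest / lam - 1.0))
                if worst is None or f_rem < worst[1]:
                    worst = (feat, f_rem)
            p_rem = float(stats.f.sf(worst[1], g - 1, n - g - len(entered) + 1))
            if p_rem < p_remove or worst[0] == entered[-1]:
                break
            entered.remove(worst[0])
            lam = naive_wilks(X, y, entered)
    return tuple(entered)


def gaussian_lda_predict(X_train, y_train, X_new, features):
    """Two-class linear discriminant from the multivariate normal score.

    Assigns by the larger of ``m_k' S^-1 x - 0.5 m_k' S^-1 m_k`` with the
    pooled covariance S — the direct density formula, no stepwise involved.
    """
    groups = sorted(pd.unique(y_train))
    vals = X_train[list(features)].to_numpy(dtype=float)
    n, g = len(vals), len(groups)
    W = np.zeros((vals.shape[1], vals.shape[1]))
    means = {}
    for grp in groups:
        sub = vals[(y_train == grp).to_numpy()]
        means[grp] = sub.mean(axis=0)
        c = sub - means[grp]
        W += c.T @ c
    S_inv = np.linalg.inv(W / (n - g))
    out = []
    for x in X_new[list(features)].to_numpy(dtype=float):
        scores = [means[grp] @ S_inv @ x - 0.5 * means[grp] @ S_inv @ means[grp]
                  for grp in groups]
        out.append(groups[int(np.argmax(scores))])
    return pd.Series(out, index=X_new.index)
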