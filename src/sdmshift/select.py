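"""Collinearity pruning of environmental predictors.

Two filters applied in sequence: a pairwise Spearman rank-correlation
filter (|rho| > 0.85 drops one member of the pair) followed by stepwise
variance-inflation-factor elimination (drop the max-VIF predictor while
max VIF > 5).  Categorical layers bypass both filters — rank correlation
and OLS are ill-defined on unordered codes — and are noted as exempt in
the report.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .grid import EnvStack

__all__ = ["SelectionReport", "spearman_matrix", "prune_spearman",
           "vif_stepwise", "select_predictors", "vif_values"]

logger = logging.getLogger(__name__)


@dataclass
class SelectionReport:
    kept: list[str]
    dropped: list[dict] = field(default_factory=list)  # {name, reason, value, partner?}
    exempt: list[str] = field(default_factory=list)    # categorical bypass
    rho_threshold: float = 0.85
    vif_threshold: float = 5.0

    def drop(self, name: str, reason: str, value: float, partner: str | None = None) -> None:
        entry = {"name": name, "reason": reason, "value": float(value)}
        if partner is not None:
            entry["partner"] = partner
        self.dropped.append(entry)
        self.kept.remove(name)

    def to_dict(self) -> dict:
        return {
            "kept": list(self.kept),
            "dropped": list(self.dropped),
            "exempt": list(self.exempt),
            "thresholds": {"spearman": self.rho_threshold, "vif": self.vif_threshold},
        }


def _continuous_matrix(stack: EnvStack, names: list[str] | None = None
                       ) -> tuple[np.ndarray, list[str]]:
    names = names if names is not None else [
        n for n in stack.names if stack[n].kind == "continuous"]
    X, _ = stack.feature_matrix(names)
    return X, names


def spearman_matrix(stack: EnvStack, names: list[str] | None = None) -> tuple[np.ndarray, list[str]]:
    """Spearman rank-correlation matrix over unmasked cells.

    Ties receive average ranks.  A constant layer has undefined rank
    correlation; its entries are reported as 0 with a warning.
    """
    X, names = _continuous_matrix(stack, names)
    if X.shape[0] < 3:
        raise ValueError("need at least 3 unmasked cells for rank correlation")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rho = stats.spearmanr(X, axis=0).statistic
    rho = np.atleast_2d(np.asarray(rho, dtype=float))
    if rho.shape != (len(names), len(names)):  # spearmanr collapses for 2 layers
        r = rho.item() if rho.size == 1 else rho[0, 1]
        rho = np.array([[1.0, r], [r, 1.0]])
    bad = ~np.isfinite(rho)
    if np.any(bad):
        logger.warning("constant layer(s): undefined Spearman correlations reported as 0")
        rho = np.where(bad, 0.0, rho)
        np.fill_diagonal(rho, 1.0)
    return rho, names


def prune_spearman(stack: EnvStack, threshold: float = 0.85) -> SelectionReport:
    """Drop layers until no pair has |rho| above the threshold.

    For the worst offending pair, the member with the larger mean absolute
    correlation to all other remaining layers is dropped; ties break by
    layer input order (the later layer goes).
    """
    continuous = [n for n in stack.names if stack[n].kind == "continuous"]
    exempt = [n for n in stack.names if stack[n].kind == "categorical"]
    report = SelectionReport(kept=list(stack.names), exempt=exempt, rho_threshold=threshold)
    active = list(continuous)
    while len(active) >= 2:
        rho, _ = spearman_matrix(stack, active)
        a = np.abs(rho)
        np.fill_diagonal(a, 0.0)
        i, j = np.unravel_index(np.argmax(a), a.shape)
        if a[i, j] <= threshold:
            break
        mean_i = a[i].sum() / (len(active) - 1)
        mean_j = a[j].sum() / (len(active) - 1)
        # near-ties (within float summation noise) drop the later layer
        if abs(mean_i - mean_j) <= 1e-9:
            victim = max(i, j)
        else:
            victim = i if mean_i > mean_j else j
        partner = j if victim == i else i
        report.drop(active[victim], "spearman", rho[i, j], partner=active[partner])
        del active[victim]
    return report


def vif_values(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1 / (1 - R^2_j) from OLS of column j on the other columns."""
    n, p = X.shape
    vifs = np.empty(p)
    ones = np.ones((n, 1))
    for j in range(p):
        y = X[:, j]
        others = np.hstack([ones, np.delete(X, j, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0.0:
            vifs[j] = 1.0  # constant column: no variance to inflate
            continue
        r2 = 1.0 - ss_res / ss_tot
        vifs[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return vifs


def vif_stepwise(stack: EnvStack, threshold: float = 5.0,
                 start: list[str] | None = None) -> SelectionReport:
    """Stepwise VIF elimination: drop the max-VIF layer while max > threshold.

    Exactly collinear layers have infinite VIF and are dropped first; ties
    break by layer input order (the later layer goes).
    """
    continuous = [n for n in (start or stack.names) if stack[n].kind == "continuous"]
    exempt = [n for n in (start or stack.names) if stack[n].kind == "categorical"]
    report = SelectionReport(kept=list(start or stack.names), exempt=exempt,
                             vif_threshold=threshold)
    active = list(continuous)
    while len(active) >= 2:
        X, _ = stack.feature_matrix(active)
        if X.shape[0] <= len(active):
            raise ValueError("need more unmasked cells than layers for VIF")
        vifs = vif_values(X)
        worst = int(np.lexsort((np.arange(len(active)), vifs))[-1])
        if vifs[worst] <= threshold:
            break
        report.drop(active[worst], "vif", vifs[worst])
        del active[worst]
    return report


def select_predictors(stack: EnvStack, rho_threshold: float = 0.85,
                      vif_threshold: float = 5.0) -> SelectionReport:
    """Spearman prune followed by stepwise VIF; the standard two-stage filter."""
    rep1 = prune_spearman(stack, rho_threshold)
    rep2 = vif_stepwise(stack, vif_threshold, start=rep1.kept)
    merged = SelectionReport(kept=list(rep2.kept), dropped=rep1.dropped + rep2.dropped,
                             exempt=rep1.exempt, rho_threshold=rho_threshold,
                             vif_threshold=vif_threshold)
    return merged
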