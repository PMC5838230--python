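"""Univariate hit calling: normality screening, Wilcoxon rank-sum tests
against set-specific controls, BH-FDR correction and directional categories.

Each knockdown population is compared to the internal control of its own
experimental set, one test per trait (size = area, symmetry = circularity).
Rank tests are invariant to the monotone log/logit transforms, so they run on
the raw trait values. Significant populations are labelled by the direction
of the median change: small / large for size, loss of symmetry / improved
symmetry for circularity.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator
from statsmodels.stats.diagnostic import lilliefors

from .io import ScreenDataset

TRAITS = {"size": "area", "symmetry": "circularity"}

#: direction -> subcategory label, per trait
SUBCATEGORY = {
    ("size", "decrease"): "small",
    ("size", "increase"): "large",
    ("symmetry", "decrease"): "loss of symmetry",
    ("symmetry", "increase"): "improved symmetry",
}

# exact Wilcoxon null only for small tie-free samples; matches common
# statistical-package behaviour
EXACT_LIMIT = 25


@dataclasses.dataclass
class UnivariateResult:
    set_id: str
    population_id: str
    trait: str
    statistic: float  # rank-sum W of the knockdown sample
    p_value: float
    q_value: float = float("nan")
    direction: str = "none"
    significant: bool = False

    @property
    def subcategory(self) -> str | None:
        if not self.significant:
            return None
        return SUBCATEGORY[(self.trait, self.direction)]


def wilcoxon_vs_control(pop_values, control_values) -> tuple[float, float, str]:
    """Two-sided Wilcoxon rank-sum test of a knockdown vs its control.

    Returns ``(W, p, direction)`` where W is the rank-sum of the knockdown
    sample in the pooled ranking and direction is the sign of the median
    difference (``"increase"``, ``"decrease"`` or ``"none"``).

    The exact null distribution is used when n + m <= 25 and the pooled
    sample is tie-free; otherwise the normal approximation with continuity
    and tie correction.
    """
    x = np.asarray(pop_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= EXACT_LIMIT and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + x.size * (x.size + 1) / 2.0  # U -> rank-sum W
    diff = float(np.median(x) - np.median(y))
    direction = "none" if diff == 0 else ("increase" if diff > 0 else "decrease")
    return w, float(res.pvalue), direction


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; input order preserved.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def normality_screen(
    ds: ScreenDataset, condition: str, alpha: float = 0.05, min_n: int = 3
) -> pd.DataFrame:
    """Shapiro-Wilk and Lilliefors (KS-type) normality tests per population
    per raw trait.

    Returns a long DataFrame with one row per (set, population, trait);
    populations with fewer than ``min_n`` values or zero variance are flagged
    ``degenerate`` and excluded from the normal-fraction summary
    (``frame.attrs["fraction_normal"]``, keyed by trait, at level ``alpha``).
    """
    rows = []
    for set_id, pop in ds.populations(condition):
        for trait, column in TRAITS.items():
            vals = ds.trait_values(set_id, pop, condition, column)
            degenerate = vals.size < min_n or np.ptp(vals) == 0
            if degenerate:
                sw_stat = sw_p = ks_stat = ks_p = float("nan")
            else:
                sw_stat, sw_p = stats.shapiro(vals)
                if vals.size >= 4:  # Lilliefors needs >= 4 observations
                    ks_stat, ks_p = lilliefors(vals, dist="norm")
                else:
                    ks_stat = ks_p = float("nan")
            rows.append(
                {
                    "set_id": set_id,
                    "population_id": pop,
                    "trait": trait,
                    "n": int(vals.size),
                    "shapiro_stat": float(sw_stat),
                    "shapiro_p": float(sw_p),
                    "ks_stat": float(ks_stat),
                    "ks_p": float(ks_p),
                    "degenerate": bool(degenerate),
                }
            )
    frame = pd.DataFrame(rows)
    fractions = {}
    for trait in TRAITS:
        sub = frame[(frame["trait"] == trait) & ~frame["degenerate"]]
        fractions[trait] = (
            float((sub["shapiro_p"] > alpha).mean()) if len(sub) else float("nan")
        )
    frame.attrs["alpha"] = alpha
    frame.attrs["fraction_normal"] = fractions
    return frame


def categorize_hits(results: pd.DataFrame) -> pd.DataFrame:
    """Collapse per-trait univariate results into one row per population with
    its subcategory labels (a population may carry one size and one symmetry
    label)."""
    out = []
    for (set_id, pop), grp in results.groupby(["set_id", "population_id"], sort=False):
        labels = []
        for _, row in grp.iterrows():
            if row["significant"] and row["direction"] != "none":
                labels.append(SUBCATEGORY[(row["trait"], row["direction"])])
        out.append(
            {
                "set_id": set_id,
                "population_id": pop,
                "subcategories": ";".join(sorted(labels)),
                "is_hit": bool(labels),
            }
        )
    return pd.DataFrame(out)


class UnivariateScreen(BaseEstimator):
    """Screen-wide Wilcoxon rank-sum hit calling for one oncogene condition.

    Parameters
    ----------
    condition : str, default "none"
        Oncogene condition analysed ("none" or "MYC").
    fdr_threshold : float, default 0.05
        BH false-discovery-rate cut defining hits.
    family : {"per_trait", "per_set_trait"}, default "per_trait"
        Multiple-testing family: all constructs of the condition per trait
        (screen-wide), or one family per experimental set per trait.

    Attributes
    ----------
    results_ : DataFrame
        One row per (set, knockdown population, trait) with W, p, q,
        direction, significance and subcategory.
    hits_ : DataFrame
        One row per population with its directional subcategory labels.
    normality_ : DataFrame
        Per-population normality screen (Shapiro-Wilk + Lilliefors).
    """

    def __init__(
        self,
        condition: str = "none",
        fdr_threshold: float = 0.05,
        family: str = "per_trait",
    ):
        self.condition = condition
        self.fdr_threshold = fdr_threshold
        self.family = family

    def fit(self, ds: ScreenDataset, y=None):
        if self.family not in ("per_trait", "per_set_trait"):
            raise ValueError(f"unknown multiple-testing family {self.family!r}")
        rows = []
        controls = {}
        for set_id, pop in ds.populations(self.condition):
            ctrl = controls.setdefault(
                set_id, ds.control_population(set_id, self.condition)
            )
            if pop == ctrl:
                continue
            for trait, column in TRAITS.items():
                x = ds.trait_values(set_id, pop, self.condition, column)
                c = ds.trait_values(set_id, ctrl, self.condition, column)
                w, p, direction = wilcoxon_vs_control(x, c)
                rows.append(
                    UnivariateResult(
                        set_id=set_id,
                        population_id=pop,
                        trait=trait,
                        statistic=w,
                        p_value=p,
                        direction=direction,
                    )
                )
        frame = pd.DataFrame([dataclasses.asdict(r) for r in rows])
        if not frame.empty:
            group_cols = ["trait"] if self.family == "per_trait" else ["trait", "set_id"]
            frame["q_value"] = (
                frame.groupby(group_cols, sort=False)["p_value"]
                .transform(lambda s: bh_fdr(s.to_numpy()))
            )
            frame["significant"] = frame["q_value"] < self.fdr_threshold
            frame.loc[~frame["significant"], "direction"] = "none"
            frame["subcategory"] = [
                SUBCATEGORY.get((t, d))
                for t, d in zip(frame["trait"], frame["direction"])
            ]
        self.results_ = frame
        self.hits_ = categorize_hits(frame) if not frame.empty else frame
        self.normality_ = normality_screen(ds, self.condition)
        return self

    def hit_populations(self) -> set[tuple[str, str]]:
        """Populations significant in at least one trait."""
        if self.results_.empty:
            return set()
        sig = self.results_[self.results_["significant"]]
        return {tuple(r) for r in sig[["set_id", "population_id"]].itertuples(index=False)}
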