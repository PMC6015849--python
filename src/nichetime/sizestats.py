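"""Body-size handling: resolution rules, Hartigan's dip test, size comparisons.

Body length (cm) is log10-transformed before analysis. Bimodality of the
time-shifter size distribution is tested with Hartigan & Hartigan's dip
statistic — the maximum distance between the empirical CDF and the closest
unimodal CDF — with Monte-Carlo p-values under the uniform null. Size
comparisons between shifters and typical species are GLS regressions of
log10 size on the shifter indicator, with or without a Pagel's-lambda
phylogenetic covariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import phylo
from .trees import Phylogeny

__all__ = [
    "resolve_body_size",
    "dip_statistic",
    "dip_pvalue",
    "dip_test",
    "DipResult",
    "split_by_threshold",
    "compare_sizes",
    "SizeComparison",
    "assemblage_size_difference",
]


def resolve_body_size(entries) -> float:
    """Resolve a species' body length from heterogeneous source entries.

    A ``typical`` value wins; otherwise the mean of ``min`` and ``max``;
    otherwise the mean of all available entries (e.g. sex-specific values).
    ``entries`` is a mapping (keys like typical/min/max/male/female) or a
    plain iterable of values.
    """
    if isinstance(entries, dict):
        vals = {k: v for k, v in entries.items() if v is not None and not pd.isna(v)}
        if not vals:
            raise ValueError("no body size entries")
        if "typical" in vals:
            out = float(vals["typical"])
        elif "min" in vals and "max" in vals:
            out = (float(vals["min"]) + float(vals["max"])) / 2.0
        else:
            out = float(np.mean(list(vals.values())))
    else:
        arr = [v for v in entries if v is not None and not pd.isna(v)]
        if not arr:
            raise ValueError("no body size entries")
        out = float(np.mean(arr))
    if out <= 0:
        raise ValueError("body size must be positive")
    return out


# ---------------------------------------------------------------------------
# Hartigan's dip
# ---------------------------------------------------------------------------

def _hull_indices(xs: np.ndarray, ys: np.ndarray, lower: bool) -> list[int]:
    """Monotone-chain convex hull (indices) of points sorted by x."""
    hull: list[int] = []
    for i in range(len(xs)):
        while len(hull) >= 2:
            a, b = hull[-2], hull[-1]
            cross = ((xs[b] - xs[a]) * (ys[i] - ys[a])
                     - (ys[b] - ys[a]) * (xs[i] - xs[a]))
            if (cross <= 0 and lower) or (cross >= 0 and not lower):
                hull.pop()
            else:
                break
        hull.append(i)
    return hull


def _segment_of(vertices: list[int], v: int) -> tuple[int, int]:
    """Hull segment [a, b] (vertex indices) containing position v."""
    import bisect

    k = bisect.bisect_right(vertices, v)
    if k == 0:
        return vertices[0], vertices[0]
    if k == len(vertices):
        return vertices[-1], vertices[-1]
    return vertices[k - 1], vertices[k]


def dip_statistic(sample) -> float:
    """Exact Hartigan & Hartigan dip of a univariate sample.

    Works in count units on the sorted sample: the greatest convex minorant
    uses the ECDF's left limits, the least concave majorant its right limits;
    the modal interval is narrowed iteratively and the dip is half the largest
    deviation found, floored at 1/(2n).
    """
    x = np.sort(np.asarray(sample, dtype=float))
    n = len(x)
    if n < 4:
        raise ValueError("dip needs at least 4 observations")
    if x[0] == x[-1]:
        return 1.0 / (2.0 * n)

    low, high = 0, n - 1
    d_count = 1.0  # 2n * dip, lower bound: one ECDF jump

    for _ in range(n + 1):
        idx = np.arange(low, high + 1)
        xs = x[low:high + 1]
        gcm = [low + i for i in _hull_indices(xs, idx.astype(float), lower=True)]
        lcm = [low + i for i in _hull_indices(xs, idx.astype(float) + 1.0, lower=False)]

        if len(gcm) == 2 and len(lcm) == 2:
            d = 1.0
            new_low, new_high = low, high
        else:
            # largest gap between the majorant and the minorant
            d = 0.0
            new_low, new_high = low, high
            for v in lcm:  # LCM vertex against GCM chord
                a, b = _segment_of(gcm, v)
                if b == a:
                    gap = 1.0
                else:
                    slope = (b - a) / (x[b] - x[a]) if x[b] != x[a] else 0.0
                    gap = (v - a + 1.0) - (x[v] - x[a]) * slope
                if gap > d:
                    d = gap
                    new_low, new_high = a, v
            for u in gcm:  # GCM vertex against LCM chord
                a, b = _segment_of(lcm, u)
                if b == a:
                    gap = 1.0
                else:
                    slope = (b - a) / (x[b] - x[a]) if x[b] != x[a] else 0.0
                    gap = (x[u] - x[a]) * slope - (u - a - 1.0)
                if gap > d:
                    d = gap
                    new_low, new_high = u, b

        if d <= d_count or (new_low == low and new_high == high):
            break

        # deviations of the ECDF from the hulls over the discarded flanks
        dip_l = 0.0
        for a, b in zip(gcm[:-1], gcm[1:]):
            if b <= new_low and b - a >= 1 and x[b] != x[a]:
                C = (b - a) / (x[b] - x[a])
                jj = np.arange(a, b + 1)
                t = (jj - a + 1.0) - (x[jj] - x[a]) * C
                dip_l = max(dip_l, float(t.max()))
        dip_u = 0.0
        for a, b in zip(lcm[:-1], lcm[1:]):
            if a >= new_high and b - a >= 1 and x[b] != x[a]:
                C = (b - a) / (x[b] - x[a])
                jj = np.arange(a, b + 1)
                t = (x[jj] - x[a]) * C - (jj - a - 1.0)
                dip_u = max(dip_u, float(t.max()))

        d_count = max(d_count, dip_l, dip_u)
        low, high = new_low, new_high
        if high - low < 1:
            break

    return d_count / (2.0 * n)


def dip_null_table(n: int, n_boot: int, rng: np.random.Generator) -> np.ndarray:
    """Dip statistics of ``n_boot`` uniform(0,1) samples of size ``n``."""
    return np.array([dip_statistic(rng.random(n)) for _ in range(n_boot)])


def dip_pvalue(D: float, n: int, n_boot: int = 9999,
               seed: int | None = None,
               null_dips: np.ndarray | None = None) -> float:
    """Monte-Carlo p-value of a dip value under the uniform null.

    ``p = (1 + #{dip_boot >= D}) / (n_boot + 1)`` (plus-one correction).
    A precomputed ``null_dips`` table (same ``n``) may be supplied.
    """
    if null_dips is None:
        if n_boot < 999:
            raise ValueError("n_boot must be at least 999")
        rng = np.random.default_rng(seed)
        null_dips = dip_null_table(n, n_boot, rng)
    return float((1 + np.sum(null_dips >= D)) / (len(null_dips) + 1))


@dataclass
class DipResult:
    """Dip statistic with its Monte-Carlo calibration."""

    D: float
    p_value: float
    n: int
    n_boot: int
    seed: int | None

    def summary(self) -> str:
        return (f"Hartigan dip test: D = {self.D:.4f}, p = {self.p_value:.4g} "
                f"(n = {self.n}, {self.n_boot} Monte-Carlo draws)")


def dip_test(sample, n_boot: int = 9999, seed: int | None = None) -> DipResult:
    sample = np.asarray(sample, dtype=float)
    D = dip_statistic(sample)
    p = dip_pvalue(D, len(sample), n_boot=n_boot, seed=seed)
    return DipResult(D=D, p_value=p, n=len(sample), n_boot=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# size groups and comparisons
# ---------------------------------------------------------------------------

def split_by_threshold(sizes, threshold: float = 30.0) -> dict[str, np.ndarray]:
    """Split sizes (cm) at the threshold: small < threshold <= large.

    Values exactly at the threshold go to ``large`` (documented tie rule;
    the source counts only state greater/less than 30 cm).
    """
    s = pd.Series(sizes, dtype=float)
    return {"small": s[s < threshold], "large": s[s >= threshold]}


@dataclass
class SizeComparison:
    """Shifter-minus-typical difference in log10 body length."""

    estimate: float
    p_value: float
    lambda_: float | None
    n_shifter: int
    n_typical: int
    phylogenetic: bool
    flagged: bool = False

    def summary(self) -> str:
        kind = "phylogenetic GLS" if self.phylogenetic else "OLS"
        s = (f"Size comparison ({kind}): shifters - typical = "
             f"{self.estimate:+.4f} log10 units, p = {self.p_value:.4g} "
             f"(n = {self.n_shifter} vs {self.n_typical})")
        if self.lambda_ is not None:
            s += f", lambda = {self.lambda_:.3f}"
        if self.flagged:
            s += " [singleton group: p unreliable]"
        return s


def compare_sizes(log_sizes, shifter_flags, tree: Phylogeny | None = None,
                  lambda_: float | str = "estimate") -> SizeComparison:
    """Regress log10 size on the shifter indicator, optionally with phylogeny.

    Without a tree this is ordinary least squares; with a tree it is
    lambda-GLS (PGLS) on the same design. Both groups must be nonempty;
    singleton groups return an estimate with a flagged p-value.
    """
    if isinstance(log_sizes, (dict, pd.Series)) and tree is not None:
        log_sizes = pd.Series(log_sizes).reindex(tree.tip_labels).to_numpy(float)
        shifter_flags = pd.Series(shifter_flags).reindex(tree.tip_labels)
    y = np.asarray(log_sizes, dtype=float)
    f = np.asarray(pd.Series(shifter_flags).astype(bool), dtype=bool)
    n1, n0 = int(f.sum()), int((~f).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both shifter and typical groups must be nonempty")
    flagged = (n1 == 1) or (n0 == 1)
    if tree is None:
        import statsmodels.api as sm

        X = sm.add_constant(f.astype(float))
        res = sm.OLS(y, X).fit()
        return SizeComparison(float(res.params[1]), float(res.pvalues[1]),
                              None, n1, n0, phylogenetic=False, flagged=flagged)
    res = phylo.PGLS(tree, y, f.astype(float), exog_names=["shifter"]).fit(
        lambda_=lambda_)
    return SizeComparison(float(res.params[1]), float(res.pvalues[1]),
                          float(res.lambda_), n1, n0, phylogenetic=True,
                          flagged=flagged)


def assemblage_size_difference(membership: pd.DataFrame, classified: pd.DataFrame,
                               order: str, tree: Phylogeny | None = None) -> pd.DataFrame:
    """Per-assemblage shifter-vs-typical size difference for one order.

    For every cell whose species set contains both shifters and typical
    species of ``order``, computes the difference in mean log10 body length
    (and, when a representative tree is given, the PGLS estimate on the
    pruned cell tree). Returns a frame indexed by cell with ``estimate``,
    ``estimate_pgls`` and their signs; cells lacking one group are omitted.
    The fraction of cells with a negative (phylogenetic) estimate is stored
    in ``df.attrs['fraction_negative']``.
    """
    cls = classified.set_index("species_id")
    rows = []
    for cid, sub in membership.groupby("cell_id"):
        sp = [s for s in sub["species_id"] if cls.loc[s, "order"] == order]
        if not sp:
            continue
        flags = cls.loc[sp, "shifter"].astype("boolean").fillna(False).to_numpy()
        sizes = np.log10(cls.loc[sp, "body_length_cm"].to_numpy(dtype=float))
        if flags.sum() == 0 or (~flags).sum() == 0:
            continue
        est = float(sizes[flags].mean() - sizes[~flags].mean())
        row = {"cell_id": cid, "estimate": est, "negative": est < 0}
        if tree is not None and len(sp) >= 4 and flags.sum() >= 1 and (~flags).sum() >= 1:
            sub_tree = tree.prune_to(sp)
            y = pd.Series(sizes, index=sp)
            fl = pd.Series(flags.astype(float), index=sp)
            try:
                res = phylo.PGLS(sub_tree, y, fl.reindex(sub_tree.tip_labels),
                                 exog_names=["shifter"]).fit()
                row["estimate_pgls"] = float(res.params[1])
                row["negative_pgls"] = res.params[1] < 0
            except (ValueError, np.linalg.LinAlgError):
                pass
        rows.append(row)
    df = pd.DataFrame(rows).set_index("cell_id") if rows else pd.DataFrame(
        columns=["estimate", "negative"])
    if len(df):
        col = "negative_pgls" if "negative_pgls" in df else "negative"
        df.attrs["fraction_negative"] = float(df[col].fillna(df["negative"]).mean()) \
            if col == "negative_pgls" else float(df["negative"].mean())
    return df
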