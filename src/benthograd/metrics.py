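"""Per-unit community metrics: standing stock, Hill diversity, rarefaction.

Standing stocks are numerical densities in individuals per hectare, reported
in total and per higher-taxon or feeding group.  Diversity is summarised by
Hill numbers of order 0, 1 and 2 -- morphospecies richness S, the exponential
Shannon index exp[H'] (natural log; the exponential form makes the base
immaterial) and the inverse Simpson index 1/D -- a non-increasing sequence of
"effective taxa" counts with growing sensitivity to dominance.  Expected
richness at a common number of individuals uses the exact hypergeometric
rarefaction formula evaluated in log-space.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "density",
    "hill_numbers",
    "rarefied_richness",
    "dominance_share",
    "metric_table",
]


def density(row, area_m2: float, groups: pd.Series | None = None) -> pd.Series | float:
    """Numerical density, ind/ha.

    ``row`` is a count vector (Series indexed by morphospecies).  With
    ``groups`` (a morphospecies -> label mapping) the result is a per-label
    Series; otherwise the total density is returned.
    """
    if area_m2 <= 0:
        raise ValueError("area must be > 0")
    ha = area_m2 / 1e4
    row = pd.Series(row) if not isinstance(row, pd.Series) else row
    if groups is None:
        return float(row.sum() / ha)
    lab = groups.reindex(row.index)
    return row.groupby(lab.to_numpy()).sum() / ha


def hill_numbers(counts) -> tuple:
    """Hill numbers (S, exp[H'], 1/D) of a count vector.

    All-zero input is undefined and returns (nan, nan, nan) rather than 0.
    """
    c = np.asarray(counts, dtype=float)
    if np.any(c < 0):
        raise ValueError("counts must be non-negative")
    n = c.sum()
    if n == 0:
        return (np.nan, np.nan, np.nan)
    p = c[c > 0] / n
    s = p.size
    shannon = float(-np.sum(p * np.log(p)))
    simpson = float(np.sum(p ** 2))
    return (s, float(np.exp(shannon)), 1.0 / simpson)


def rarefied_richness(counts, n: int) -> float:
    """Expected morphospecies count in a random subsample of ``n`` individuals.

    Hypergeometric expectation E[S_n] = sum_i [1 - C(N - N_i, n) / C(N, n)],
    computed with log-gamma for stability.  Requires 0 <= n <= N.
    """
    c = np.asarray(counts, dtype=np.int64)
    c = c[c > 0]
    N = int(c.sum())
    if n < 0 or n > N:
        raise ValueError(f"subsample size n={n} outside [0, {N}]")
    if n == 0:
        return 0.0

    def logC(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    terms = np.where(
        N - c >= n,
        np.exp(logC(N - c, n) - logC(N, n)),
        0.0,
    )
    return float(np.sum(1.0 - terms))


def dominance_share(row, group: str, groups: pd.Series) -> float:
    """Proportion of individuals belonging to ``group`` (nan for empty rows)."""
    row = pd.Series(row) if not isinstance(row, pd.Series) else row
    total = float(row.sum())
    if total == 0:
        return np.nan
    lab = groups.reindex(row.index)
    return float(row[(lab == group).to_numpy()].sum() / total)


def metric_table(abund, msp_info: pd.DataFrame) -> pd.DataFrame:
    """Per-unit metric table for an :class:`~benthograd.sampling.AbundanceMatrix`.

    ``msp_info`` maps morphospecies -> (group, feeding).  Columns: unit
    metadata, N, total and per-group/per-feeding densities (ind/ha), and the
    three Hill numbers.  Diversity is computed on morphospecies columns only.
    """
    counts, meta = abund.counts, abund.meta
    group_map = msp_info["group"]
    feeding_map = msp_info["feeding"]
    rows = []
    for uid, row in counts.iterrows():
        area = float(meta.loc[uid, "area_m2"])
        s, exph, invd = hill_numbers(row.to_numpy())
        rec = {
            "unit_id": uid,
            "level": meta.loc[uid, "level"],
            "replicate": int(meta.loc[uid, "replicate"]),
            "area_m2": area,
            "N": int(row.sum()),
            "density_total": density(row, area),
            "S": s,
            "expH": exph,
            "invD": invd,
        }
        by_group = density(row, area, groups=group_map)
        for g, v in by_group.items():
            rec[f"density_{g}"] = float(v)
        by_feeding = density(row, area, groups=feeding_map)
        for f, v in by_feeding.items():
            rec[f"density_feeding_{f}"] = float(v)
        rows.append(rec)
    out = pd.DataFrame(rows).set_index("unit_id")
    return out.fillna({c: 0.0 for c in out.columns if c.startswith("density_")})
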