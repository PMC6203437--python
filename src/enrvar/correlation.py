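"""Group-wise Spearman correlation structure and its remodeling.

Correlations between phenotypes are computed separately within each
housing group (never pooled, which would manufacture correlations out of
group mean differences).  Traits are ordered by hierarchical clustering
of the enriched group's correlation matrix and the same order is applied
to both groups, so the two heat maps are directly comparable; pairs are
then classified by how enrichment changed their association (sign flips,
gained/lost significance).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

MIN_PAIRWISE_N = 3


@dataclass
class CorrelationMatrix:
    """Trait x trait Spearman correlation structure for one group.

    ``rho`` and ``p`` are symmetric DataFrames indexed by trait; ``n``
    holds the pairwise-complete sample size behind each entry.  Entries
    with fewer than 3 complete pairs, or involving a constant trait, are
    NaN and listed in ``undefined_pairs``.  ``order`` is a permutation of
    the traits (by default from clustering the ENR matrix).
    """

    group: str
    traits: list[str]
    rho: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    order: list[str]
    undefined_pairs: list[tuple[str, str]]

    def reordered(self, order: list[str]) -> "CorrelationMatrix":
        """The same matrix with rows/columns permuted to ``order``."""
        if sorted(order) != sorted(self.traits):
            raise ValueError("order must be a permutation of the traits")
        return CorrelationMatrix(
            group=self.group,
            traits=self.traits,
            rho=self.rho.loc[order, order],
            p=self.p.loc[order, order],
            n=self.n.loc[order, order],
            order=list(order),
            undefined_pairs=self.undefined_pairs,
        )

    def significance_mask(self, alpha: float = 0.05) -> pd.DataFrame:
        """Boolean mask of entries with p < alpha (NaN p -> False)."""
        return self.p.lt(alpha).fillna(False)


def spearman_matrix(
    table: pd.DataFrame, group: str, traits: list[str] | None = None
) -> CorrelationMatrix:
    """Spearman rho and p between all trait pairs within one group.

    rho is Pearson correlation on midranked data; the two-tailed p comes
    from the t approximation t = rho * sqrt((n-2) / (1-rho^2)) on n-2
    degrees of freedom.  Missing values are dropped pairwise, so each
    entry uses every animal with both traits recorded.
    """
    if traits is None:
        traits = [c for c in table.columns if c not in ("animal_id", "group")]
    sub = table.loc[table["group"] == group, traits]
    m = len(traits)
    rho = np.eye(m)
    p = np.full((m, m), np.nan)
    np.fill_diagonal(p, 0.0)
    n = np.zeros((m, m), dtype=int)
    np.fill_diagonal(n, sub.notna().sum().reindex(traits).to_numpy())
    undefined: list[tuple[str, str]] = []
    for i in range(m):
        for j in range(i + 1, m):
            pair = sub[[traits[i], traits[j]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            xi, xj = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if len(pair) < MIN_PAIRWISE_N or np.ptp(xi) == 0 or np.ptp(xj) == 0:
                rho[i, j] = rho[j, i] = np.nan
                undefined.append((traits[i], traits[j]))
                continue
            r, pv = sps.spearmanr(xi, xj)
            rho[i, j] = rho[j, i] = r
            p[i, j] = p[j, i] = pv
    if undefined:
        logger.warning(
            "%s correlation matrix: %d undefined pairs (constant trait or n < %d)",
            group, len(undefined), MIN_PAIRWISE_N,
        )
    idx = pd.Index(traits, name="trait")
    return CorrelationMatrix(
        group=group,
        traits=list(traits),
        rho=pd.DataFrame(rho, index=idx, columns=idx),
        p=pd.DataFrame(p, index=idx, columns=idx),
        n=pd.DataFrame(n, index=idx, columns=idx),
        order=list(traits),
        undefined_pairs=undefined,
    )


def cluster_order(matrix: CorrelationMatrix) -> list[str]:
    """Trait order from average-linkage hierarchical clustering.

    Distance is d = 1 - rho (signed, so anticorrelated traits end up far
    apart).  Undefined rho entries are imputed as 0 for the ordering only.
    The returned leaf order — conventionally derived from the enriched
    group — should be applied to both groups' matrices for side-by-side
    display.
    """
    m = len(matrix.traits)
    if m <= 2:
        return list(matrix.traits)
    rho = matrix.rho.to_numpy(dtype=float).copy()
    rho[np.isnan(rho)] = 0.0
    np.fill_diagonal(rho, 1.0)
    dist = 1.0 - (rho + rho.T) / 2.0
    np.fill_diagonal(dist, 0.0)
    z = linkage(squareform(dist, checks=False), method="average")
    return [matrix.traits[i] for i in leaves_list(z)]


def compare_structures(
    m_ctrl: CorrelationMatrix, m_enr: CorrelationMatrix, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict]:
    """Pairwise report of how enrichment restructured trait correlations.

    For every trait pair: delta_rho = rho_ENR - rho_CTRL, a sign-change
    flag (both rho non-zero with opposite signs), and the transition of
    significance status at ``alpha`` (``stable_sig``, ``stable_ns``,
    ``sig_to_ns``, ``ns_to_sig``, or ``undefined`` where either entry is
    NaN).  Returns the per-pair table and a summary count dict.
    """
    if sorted(m_ctrl.traits) != sorted(m_enr.traits):
        raise ValueError("correlation matrices must share the same trait set")
    traits = m_ctrl.traits
    rows = []
    for i in range(len(traits)):
        for j in range(i + 1, len(traits)):
            a, b = traits[i], traits[j]
            rc, re = m_ctrl.rho.loc[a, b], m_enr.rho.loc[a, b]
            pc, pe = m_ctrl.p.loc[a, b], m_enr.p.loc[a, b]
            if np.isnan(rc) or np.isnan(re):
                transition, sign_change, drho = "undefined", False, np.nan
            else:
                drho = re - rc
                sign_change = bool(rc * re < 0)
                sc, se = pc < alpha, pe < alpha
                transition = {
                    (True, True): "stable_sig",
                    (True, False): "sig_to_ns",
                    (False, True): "ns_to_sig",
                    (False, False): "stable_ns",
                }[(bool(sc), bool(se))]
            rows.append(
                {
                    "trait_a": a,
                    "trait_b": b,
                    "rho_ctrl": rc,
                    "rho_enr": re,
                    "delta_rho": drho,
                    "p_ctrl": pc,
                    "p_enr": pe,
                    "sign_change": sign_change,
                    "transition": transition,
                }
            )
    report = pd.DataFrame(rows)
    summary = {
        "n_pairs": len(report),
        "n_sign_changes": int(report["sign_change"].sum()),
        **report["transition"].value_counts().to_dict(),
    }
    return report, summary
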