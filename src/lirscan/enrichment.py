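"""Group-level motif statistics and hypergeometric set enrichment.

The central quantity compares the fraction of LIR-motif-containing proteins
(LIRCPs, proteins with at least one hit) in a protein subset against a
universe.  With ``k`` LIRCPs among ``n`` subset proteins and ``K`` among
``N`` universe proteins:

* fold enrichment ``(k / n) / (K / N)``;
* upper-tail hypergeometric probability
  ``P(X >= k) = sum_{j=k}^{min(n, K)} C(K, j) C(N-K, n-j) / C(N, n)``,
  evaluated with exact integer arithmetic (no floating-point tail sums).

No multiple-testing correction is applied by default; Benjamini-Hochberg
q-values are available via a flag in :func:`compare_groups`.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import comb
from typing import Iterable, Literal, Mapping

import pandas as pd

from .errors import EnrichmentBoundsError, GroupError
from .scanner import MotifHit

Category = Literal["all", "xlir"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Urn parameters, fold enrichment and upper-tail probability."""

    k: int
    n: int
    K: int
    N: int
    fold: float
    p_value: float


@dataclass(frozen=True)
class GroupSummary:
    """Per-group motif statistics (family, order, host class, ...)."""

    group: str
    n_sequences: int
    n_lircp: int
    n_xlir: int
    n_wxxl: int
    subtype_counts: Mapping[str, int]
    motifs_per_sequence: float


def hypergeometric_pvalue(k: int, n: int, K: int, N: int) -> float:
    """Exact upper-tail probability ``P(X >= k)`` of Hypergeometric(N, K, n)."""
    _check_urn(k, n, K, N)
    if k == 0:
        return 1.0
    total = comb(N, n)
    upper = min(n, K)
    acc = 0
    for j in range(k, upper + 1):
        acc += comb(K, j) * comb(N - K, n - j)
    return float(Fraction(acc, total))


def _check_urn(k: int, n: int, K: int, N: int) -> None:
    for name, v in (("k", k), ("n", n), ("K", K), ("N", N)):
        if not isinstance(v, (int,)) or isinstance(v, bool):
            raise EnrichmentBoundsError(f"{name} must be an integer, got {v!r}")
    if not (0 <= n <= N and 0 <= K <= N and 0 <= k <= min(n, K)):
        raise EnrichmentBoundsError(
            f"urn bounds violated: k={k}, n={n}, K={K}, N={N}"
        )


def hypergeometric_enrichment(k: int, n: int, K: int, N: int) -> EnrichmentResult:
    """Fold enrichment and exact upper-tail p-value for one subset.

    Fold is ``(k/n) / (K/N)``; NaN when the subset is empty, and infinity
    when ``K = 0`` but ``k > 0`` is impossible by the bounds, so ``K = 0``
    simply yields fold NaN.
    """
    _check_urn(k, n, K, N)
    if n == 0 or K == 0 or N == 0:
        fold = float("nan")
    else:
        fold = (k / n) / (K / N)
    return EnrichmentResult(
        k=k, n=n, K=K, N=N, fold=fold, p_value=hypergeometric_pvalue(k, n, K, N)
    )


def subtype_distribution(
    hits: Iterable[MotifHit] | pd.DataFrame,
    groupby: str | None = None,
) -> pd.DataFrame:
    """W/F/Y proportions per pattern class (rows sum to 1).

    Accepts either :class:`~lirscan.scanner.MotifHit` objects or a hit table
    with ``pattern_class`` and ``subtype`` columns.  With ``groupby`` (a
    column of the table) proportions are computed per group and class.
    """
    if isinstance(hits, pd.DataFrame):
        df = hits
    else:
        df = pd.DataFrame(
            [{"pattern_class": h.pattern_class, "subtype": h.subtype} for h in hits]
        )
    if df.empty:
        raise GroupError("cannot compute a subtype distribution of zero hits")
    keys = ([groupby] if groupby else []) + ["pattern_class"]
    counts = (
        df.groupby(keys + ["subtype"], sort=True).size().unstack(fill_value=0)
    )
    for st in "WFY":
        if st not in counts.columns:
            counts[st] = 0
    counts = counts[list("WFY")]
    props = counts.div(counts.sum(axis=1), axis=0)
    return props.reset_index()


def lircp_table(
    summaries: pd.DataFrame, category: Category = "all"
) -> pd.Series:
    """Boolean LIRCP flag per protein from a scanner summary table.

    ``"all"`` counts any motif; ``"xlir"`` requires at least one xLIR hit.
    """
    if category == "all":
        flag = summaries["motifs_total"] > 0
    elif category == "xlir":
        flag = summaries["n_xlir"] > 0
    else:
        raise GroupError(f"unknown category {category!r}")
    return pd.Series(flag.to_numpy(), index=summaries["protein_id"].to_numpy())


def compare_groups(
    groups: Mapping[str, Iterable[str]] | pd.DataFrame,
    lircp: pd.Series,
    categories: tuple[Category, ...] = ("all",),
    summaries: pd.DataFrame | None = None,
    fdr: bool = False,
) -> pd.DataFrame:
    """One :class:`EnrichmentResult` row per group per motif category.

    Parameters
    ----------
    groups
        Mapping group label -> protein ids, or a DataFrame with columns
        ``protein_id`` and ``group``.  Every group must be a subset of the
        universe (the index of ``lircp``).
    lircp
        Boolean Series indexed by protein id: the "all"-category LIRCP flag
        over the whole universe.
    categories
        Which flags to test; ``"xlir"`` needs ``summaries`` to recompute the
        flag per category.
    fdr
        Append a Benjamini-Hochberg ``q_value`` column.
    """
    if isinstance(groups, pd.DataFrame):
        mapping: dict[str, list[str]] = {
            str(g): sub["protein_id"].tolist()
            for g, sub in groups.groupby("group", sort=True)
        }
    else:
        mapping = {str(g): list(ids) for g, ids in groups.items()}

    universe = set(lircp.index)
    rows = []
    for category in categories:
        if category == "all":
            flag = lircp
        else:
            if summaries is None:
                raise GroupError("category 'xlir' requires the summary table")
            flag = lircp_table(summaries, category)
        K = int(flag.sum())
        N = len(universe)
        positives = set(flag.index[flag])
        for label in sorted(mapping):
            members = set(mapping[label])
            stray = members - universe
            if stray:
                raise GroupError(
                    f"group {label!r} has {len(stray)} proteins outside the universe"
                )
            n = len(members)
            k = len(members & positives)
            res = hypergeometric_enrichment(k, n, K, N)
            rows.append(
                {
                    "group": label,
                    "category": category,
                    "k": res.k,
                    "n": res.n,
                    "K": res.K,
                    "N": res.N,
                    "fold": res.fold,
                    "p_value": res.p_value,
                }
            )
    out = pd.DataFrame(rows)
    if fdr and not out.empty:
        from statsmodels.stats.multitest import multipletests

        out["q_value"] = multipletests(out["p_value"], method="fdr_bh")[1]
    return out


def summarize_group(
    group: str,
    hits: pd.DataFrame,
    n_sequences: int,
) -> GroupSummary:
    """Aggregate one group's hit table into a :class:`GroupSummary`."""
    if n_sequences <= 0:
        raise GroupError(f"group {group!r} has no sequences")
    n_xlir = int((hits["pattern_class"] == "xLIR").sum())
    n_wxxl = int((hits["pattern_class"] == "WxxL").sum())
    subtype_counts = hits["subtype"].value_counts().to_dict()
    n_lircp = hits["accession"].nunique()
    return GroupSummary(
        group=group,
        n_sequences=n_sequences,
        n_lircp=n_lircp,
        n_xlir=n_xlir,
        n_wxxl=n_wxxl,
        subtype_counts=subtype_counts,
        motifs_per_sequence=len(hits) / n_sequences,
    )
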