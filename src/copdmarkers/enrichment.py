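"""Gene-set over-representation by the one-sided Fisher's exact test.

Given a query gene list (e.g. a biomarker panel) and a collection of
gene sets (GO terms or pathways in GMT format), each set is tested for
containing more of the query than expected by chance: the p-value is the
hypergeometric upper tail P(X >= k) with k the observed overlap, n the
query size, K the set size within the universe and N the universe size.
The universe is the set of genes actually measured (all genes on the
normalized matrix), not the genome.  Benjamini-Hochberg adjustment is
applied within each annotation domain; the enrichment score is
-log10(p), the conventional display scale.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

DOMAINS = (
    "biological_process",
    "cellular_component",
    "molecular_function",
    "pathway",
    "other",
)

RESULT_COLUMNS = ("set_id", "name", "domain", "k", "n", "K", "N", "p", "q",
                  "enrichment_score")


class EnrichmentError(ValueError):
    """Raised for invalid queries, universes or gene-set files."""


@dataclass(frozen=True)
class GeneSet:
    set_id: str
    name: str
    domain: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise EnrichmentError(f"gene set {self.set_id!r} has no members")
        if self.domain not in DOMAINS:
            raise EnrichmentError(
                f"gene set {self.set_id!r}: unknown domain {self.domain!r}"
            )


@dataclass(frozen=True)
class EnrichmentResult:
    set_id: str
    name: str
    domain: str
    k: int
    n: int
    K: int
    N: int
    p: float
    q: float
    enrichment_score: float


def read_gmt(path: str, domain: str = "other") -> list[GeneSet]:
    """Parse a GMT file: per line, set id, description, then member genes."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise EnrichmentError(
                    f"{path}:{lineno}: GMT line needs id, description and "
                    f"at least one member"
                )
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise EnrichmentError(f"{path}:{lineno}: gene set has no members")
            sets.append(GeneSet(fields[0], fields[1], domain, members))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.name, *sorted(s.members)]) + "\n")


def _validate_query(query: Sequence[str], universe: Sequence[str]) -> tuple[set, set]:
    uni = set(universe)
    if not uni:
        raise EnrichmentError("universe is empty")
    q = set(query)
    offenders = sorted(q - uni)
    if offenders:
        raise EnrichmentError(f"query gene(s) not in universe: {offenders}")
    return q, uni


def fisher_overrepresentation(
    query: Sequence[str], gene_set: GeneSet, universe: Sequence[str]
) -> EnrichmentResult:
    """One-sided over-representation p-value for a single gene set.

    Set members are intersected with the universe before testing; the
    p-value is the hypergeometric upper tail
    ``p = sum_{i=k}^{min(n, K)} C(K,i) C(N-K,n-i) / C(N,n)``.
    """
    q, uni = _validate_query(query, universe)
    members = gene_set.members & uni
    K, N, n = len(members), len(uni), len(q)
    k = len(q & members)
    p = float(stats.hypergeom.sf(k - 1, N, K, n))
    p = min(p, 1.0)
    return EnrichmentResult(
        gene_set.set_id, gene_set.name, gene_set.domain,
        k, n, K, N, p, q=math.nan,
        enrichment_score=0.0 if p >= 1 else -math.log10(p),
    )


def enrich_all(
    query: Sequence[str], sets: Iterable[GeneSet], universe: Sequence[str]
) -> pd.DataFrame:
    """Test every gene set; BH-adjust within each domain; sort by p.

    Sets with no member inside the universe are dropped.  Ties in p are
    broken by set id so output order is stable.
    """
    _validate_query(query, universe)
    uni = set(universe)
    results = [
        fisher_overrepresentation(query, s, universe)
        for s in sets
        if s.members & uni
    ]
    if not results:
        return pd.DataFrame(columns=list(RESULT_COLUMNS))
    table = pd.DataFrame([r.__dict__ for r in results], columns=list(RESULT_COLUMNS))
    for domain in table["domain"].unique():
        mask = table["domain"] == domain
        table.loc[mask, "q"] = multipletests(
            table.loc[mask, "p"], method="fdr_bh"
        )[1]
    return table.sort_values(["p", "set_id"], ignore_index=True)
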