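"""Over-representation analysis (ORA) of gene sets against GMT collections.

For a query gene set of size n drawn from a universe of N genes, and an
annotation set covering K universe genes of which k are in the query, the
enrichment p-value is the upper hypergeometric tail P(X >= k). An EASE-style
variant (the modified Fisher score used by DAVID, which discounts one
overlapping gene) is available. BH-FDR is applied across sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from scipy import stats

from .datatypes import ValidationError
from .diffexpr import bh_fdr


@dataclass
class GeneSetCollection:
    """Named gene sets with descriptions (GMT semantics)."""

    sets: dict = field(default_factory=dict)
    descriptions: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValidationError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file (name <tab> description <tab> member...).

    Duplicate members within a set are stored once; a line with fewer than
    three fields is an error reported with its line number.
    """
    sets, descriptions = {}, {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValidationError(
                f"GMT line {lineno}: expected >= 3 tab-separated fields, "
                f"got {len(fields)}")
        name, desc, *members = fields
        if name in sets:
            raise ValidationError(f"GMT line {lineno}: duplicate set name {name!r}")
        seen = []
        for m in members:
            if m and m not in seen:
                seen.append(m)
        sets[name] = seen
        descriptions[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    lines = []
    for name, members in collection.sets.items():
        desc = collection.descriptions.get(name, "")
        lines.append("\t".join([name, desc, *members]))
    Path(path).write_text("\n".join(lines) + "\n")


def ora_test(query_genes, universe_genes, collection: GeneSetCollection,
             method: str = "hypergeom") -> pd.DataFrame:
    """Over-representation test of ``query_genes`` against each set.

    Query genes outside the universe are dropped (recorded in
    ``result.attrs['dropped']``); set members are intersected with the
    universe. Returns a table sorted by p with columns set_name, k, K, n, N,
    p, fdr, enriched_genes.
    """
    if method not in ("hypergeom", "ease"):
        raise ValidationError("method must be 'hypergeom' or 'ease'")
    universe = set(universe_genes)
    dropped = sorted(set(query_genes) - universe)
    query = set(query_genes) & universe
    if not query:
        raise ValidationError("query is empty after universe intersection")
    N, n = len(universe), len(query)
    rows = []
    for name, members in collection.sets.items():
        members_u = sorted(set(members) & universe)
        K = len(members_u)
        hits = sorted(query & set(members_u))
        k = len(hits)
        kk = max(k - 1, 0) if method == "ease" else k
        # P(X >= kk) upper tail; sf(kk - 1) == P(X > kk - 1)
        p = float(stats.hypergeom.sf(kk - 1, N, K, n)) if K else 1.0
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N,
                     "p": min(p, 1.0), "enriched_genes": ",".join(hits)})
    table = pd.DataFrame(rows)
    table["fdr"] = bh_fdr(table["p"].to_numpy())
    table = table.sort_values(["p", "set_name"], kind="stable",
                              ignore_index=True)
    table = table[["set_name", "k", "K", "n", "N", "p", "fdr",
                   "enriched_genes"]]
    table.attrs["dropped"] = dropped
    return table


@dataclass
class EnrichmentResults:
    table: pd.DataFrame
    method: str

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < 0.05]

    def summary(self) -> str:
        return (f"ORA ({self.method}): {len(self.table)} sets tested, "
                f"{len(self.significant)} at P < 0.05")


class OverRepresentation:
    """ORA model: query + universe + collection -> EnrichmentResults."""

    def __init__(self, query_genes, universe_genes,
                 collection: GeneSetCollection, method: str = "hypergeom"):
        self.query = list(query_genes)
        self.universe = list(universe_genes)
        self.collection = collection
        self.method = method

    def fit(self) -> EnrichmentResults:
        table = ora_test(self.query, self.universe, self.collection,
                         self.method)
        return EnrichmentResults(table=table, method=self.method)
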