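"""Gene-set over-representation for parent genes of differential circRNAs.

A generic local hypergeometric test over user-supplied term maps (GMT or
two-column TSV); no remote annotation service is consulted, so results
are reproducible against a pinned map. The p-value kernel is the same
upper-tail routine the ceRNA module uses, with the mapping
(M_T, m_n, m_p, m_c) = (universe size N, term size K, study size n,
study hits k). The universe defaults to every gene carrying at least one
annotation in the map.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cerna import shared_mirna_pvalue

__all__ = ["TermMap", "read_term_map", "enrich"]


@dataclass(frozen=True)
class TermMap:
    term_id: str
    term_name: str
    member_genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_genes:
            raise ValueError(f"term {self.term_id} has no member genes")


def read_term_map(path: str | Path) -> list[TermMap]:
    """Read GMT (term, description, genes...) or 2-column TSV (term, gene)."""
    path = Path(path)
    terms: dict[str, set[str]] = {}
    names: dict[str, str] = {}
    with open(path) as handle:
        first = handle.readline()
        handle.seek(0)
        is_gmt = path.suffix == ".gmt" or len(first.rstrip("\n").split("\t")) > 2
        if is_gmt:
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                terms[parts[0]] = set(g for g in parts[2:] if g)
                names[parts[0]] = parts[1]
        else:
            header = handle.readline().rstrip("\n").split("\t")
            has_header = header[:1] == ["term_id"]
            if not has_header and len(header) >= 2:
                terms.setdefault(header[0], set()).add(header[1])
            for line in handle:
                parts = line.rstrip("\n").split("\t")
                if len(parts) >= 2:
                    terms.setdefault(parts[0], set()).add(parts[1])
    return [
        TermMap(t, names.get(t, t), frozenset(genes))
        for t, genes in sorted(terms.items())
    ]


def enrich(
    study_genes: Iterable[str],
    term_maps: Sequence[TermMap],
    universe: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the study set in each term.

    Returns one row per term: term_id, term_name, k (study genes in the
    term), n (study size), K (universe genes in the term), N (universe
    size), p_value (upper tail), adjusted_p (Benjamini-Hochberg),
    sorted by p_value then term_id.
    """
    study = set(study_genes)
    if universe is None:
        universe_set = set().union(*(t.member_genes for t in term_maps)) if term_maps else set()
    else:
        universe_set = set(universe)
    outside = study - universe_set
    if outside:
        raise ValueError(
            f"study genes outside the universe: {sorted(outside)[:10]}"
        )
    N, n = len(universe_set), len(study)
    rows = []
    for term in term_maps:
        members = term.member_genes & universe_set
        K = len(members)
        k = len(members & study)
        p = shared_mirna_pvalue(N, n, K, k) if K else 1.0
        rows.append(
            {"term_id": term.term_id, "term_name": term.term_name,
             "k": k, "n": n, "K": K, "N": N, "p_value": p}
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "n", "K", "N", "p_value"]
    )
    if len(result):
        result["adjusted_p"] = multipletests(result["p_value"], method="fdr_bh")[1]
    else:
        result["adjusted_p"] = pd.Series(dtype=float)
    return result.sort_values(["p_value", "term_id"]).reset_index(drop=True)
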