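"""ceRNA inference: seed-site prediction, scoring, and the network.

A miRNA response element (MRE) is an exact reverse-complement match of
the miRNA seed (positions 2-8, a 7-mer by default) in an RNA sequence;
non-overlapping occurrences are counted greedily left to right. For a
circRNA/mRNA pair sharing miRNAs, the ceRNA score is the fraction of the
circRNA's MREs that belong to shared miRNAs:

    ceRNA_score = (# circRNA MREs of shared miRNAs) / (# circRNA MREs, all miRNAs)

and the significance of sharing m_c of the M_T analysis miRNAs, when the
mRNA is targeted by m_p and the circRNA by m_n of them, is the
hypergeometric upper tail

    p = sum_{i = m_c}^{min(m_p, m_n)} C(m_n, i) C(M_T - m_n, m_p - i) / C(M_T, m_p)

evaluated in log space. Pairs with fewer than 3 shared miRNAs or p above
0.05 are filtered out; survivors are ranked by score (desc), then shared
miRNA count (desc), then pair id.

The full miRanda alignment/energy model is deliberately replaced by
exact seed matching: the scoring above consumes only MRE counts, which
seed matching supplies deterministically. The numerator convention
(circRNA-side MREs only) is isolated in :func:`cerna_score` so an
mRNA-side-inclusive variant can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp, lgamma
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from ._seq import revcomp

__all__ = [
    "predict_mres",
    "predict_mres_table",
    "cerna_score",
    "shared_mirna_pvalue",
    "CeRNAPair",
    "NetworkThresholds",
    "score_pairs",
    "filter_pairs",
    "build_network",
]

DEFAULT_SEED_SPAN = (1, 8)  # miRNA positions 2-8, 0-based half-open


def seed_site(mirna_seq: str, seed_span: tuple[int, int] = DEFAULT_SEED_SPAN) -> str:
    """The RNA-side site: reverse complement of the miRNA seed."""
    start, end = seed_span
    if len(mirna_seq) < end:
        raise ValueError(
            f"miRNA sequence of length {len(mirna_seq)} shorter than seed span {seed_span}"
        )
    return revcomp(mirna_seq[start:end].upper().replace("U", "T"))


def predict_mres(
    rna_sequence: str,
    mirna_sequences: Mapping[str, str],
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
) -> dict[str, list[int]]:
    """Seed-complement sites per miRNA in one RNA sequence.

    Occurrences are counted greedily left to right without overlap.
    Only miRNAs with at least one site appear in the result.
    """
    rna = rna_sequence.upper().replace("U", "T")
    out: dict[str, list[int]] = {}
    for mirna_id in sorted(mirna_sequences):
        site = seed_site(mirna_sequences[mirna_id], seed_span)
        positions: list[int] = []
        i = rna.find(site)
        while i != -1:
            positions.append(i)
            i = rna.find(site, i + len(site))  # greedy non-overlapping
        if positions:
            out[mirna_id] = positions
    return out


def predict_mres_table(
    sequences: Mapping[str, str],
    rna_class: str,
    mirna_sequences: Mapping[str, str],
    seed_span: tuple[int, int] = DEFAULT_SEED_SPAN,
) -> pd.DataFrame:
    """MRE table rows (rna_id, rna_class, mirna_id, site_count, positions)
    for a whole FASTA's worth of sequences."""
    rows = []
    for rna_id in sequences:
        for mirna_id, positions in predict_mres(
            sequences[rna_id], mirna_sequences, seed_span
        ).items():
            rows.append(
                {
                    "rna_id": rna_id,
                    "rna_class": rna_class,
                    "mirna_id": mirna_id,
                    "site_count": len(positions),
                    "positions": ",".join(map(str, positions)),
                }
            )
    return pd.DataFrame(
        rows, columns=["rna_id", "rna_class", "mirna_id", "site_count", "positions"]
    )


def cerna_score(
    circ_site_counts: Mapping[str, int], shared_mirnas: Sequence[str]
) -> float:
    """Fraction of the circRNA's MREs that belong to shared miRNAs.

    The denominator is the circRNA's total MRE count over all its
    targeting miRNAs; mRNA-side sites do not enter. A circRNA with no
    MREs at all is not a ceRNA candidate and raises ValueError rather
    than dividing by zero.
    """
    total = sum(circ_site_counts.values())
    if total <= 0:
        raise ValueError("circRNA has no MREs; pair is not a ceRNA candidate")
    shared = set(shared_mirnas)
    num = sum(c for m, c in circ_site_counts.items() if m in shared)
    return num / total


def _log_comb(n: int, k: int) -> float:
    return lgamma(n + 1) - lgamma(k + 1) - lgamma(n - k + 1)


def shared_mirna_pvalue(M_T: int, m_p: int, m_n: int, m_c: int) -> float:
    """Hypergeometric upper-tail probability of sharing >= m_c miRNAs.

    Drawing the mRNA's m_p targeting miRNAs from the M_T analysis
    universe of which m_n target the circRNA, this is
    P(overlap >= m_c), evaluated by a log-space sum of the tail terms.
    """
    if not (0 <= m_p <= M_T and 0 <= m_n <= M_T):
        raise ValueError("require 0 <= m_p, m_n <= M_T")
    if not 0 <= m_c <= min(m_p, m_n):
        raise ValueError("require 0 <= m_c <= min(m_p, m_n)")
    if m_c == 0:
        return 1.0
    log_denom = _log_comb(M_T, m_p)
    log_terms = [
        _log_comb(m_n, i) + _log_comb(M_T - m_n, m_p - i) - log_denom
        for i in range(m_c, min(m_p, m_n) + 1)
        if m_p - i <= M_T - m_n  # C(n, k) = 0 beyond its support
    ]
    if not log_terms:
        return 0.0
    peak = max(log_terms)
    return min(1.0, exp(peak) * sum(exp(t - peak) for t in log_terms))


@dataclass(frozen=True)
class CeRNAPair:
    circ_id: str
    mrna_id: str
    M_T: int
    m_p: int
    m_n: int
    m_c: int
    shared_mirnas: tuple[str, ...]
    cerna_score: float
    p_value: float

    def __post_init__(self) -> None:
        if not self.m_c <= min(self.m_p, self.m_n) <= self.M_T:
            raise ValueError("inconsistent miRNA counts")
        if len(self.shared_mirnas) != self.m_c:
            raise ValueError("shared miRNA list does not match m_c")


@dataclass
class NetworkThresholds:
    """Retention rule: pairs with fewer shared miRNAs than ``min_shared``
    or p above ``max_p`` are filtered out (both bounds inclusive on the
    keep side). Benjamini-Hochberg adjustment of pair p-values is off by
    default; the filter acts on raw p."""

    min_shared: int = 3
    max_p: float = 0.05
    adjust_p: bool = False


def score_pairs(mre_table: pd.DataFrame, M_T: int | None = None) -> list[CeRNAPair]:
    """Score every circRNA x mRNA pair with at least one shared miRNA.

    ``mre_table`` needs columns rna_id, rna_class ('circRNA'/'mRNA'),
    mirna_id, site_count. M_T defaults to the number of distinct miRNAs
    in the table (the analysis universe).
    """
    required = {"rna_id", "rna_class", "mirna_id", "site_count"}
    if missing := required - set(mre_table.columns):
        raise ValueError(f"MRE table missing columns {sorted(missing)}")
    if M_T is None:
        M_T = int(mre_table["mirna_id"].nunique())
    circ_rows = mre_table[mre_table["rna_class"] == "circRNA"]
    mrna_rows = mre_table[mre_table["rna_class"] == "mRNA"]

    circ_sites: dict[str, dict[str, int]] = {
        rna: dict(zip(g["mirna_id"], g["site_count"]))
        for rna, g in circ_rows.groupby("rna_id", sort=True)
    }
    mrna_sites: dict[str, dict[str, int]] = {
        rna: dict(zip(g["mirna_id"], g["site_count"]))
        for rna, g in mrna_rows.groupby("rna_id", sort=True)
    }

    pairs: list[CeRNAPair] = []
    for circ_id, csites in circ_sites.items():
        for mrna_id, msites in mrna_sites.items():
            shared = sorted(set(csites) & set(msites))
            if not shared:
                continue
            pairs.append(
                CeRNAPair(
                    circ_id=circ_id,
                    mrna_id=mrna_id,
                    M_T=M_T,
                    m_p=len(msites),
                    m_n=len(csites),
                    m_c=len(shared),
                    shared_mirnas=tuple(shared),
                    cerna_score=cerna_score(csites, shared),
                    p_value=shared_mirna_pvalue(M_T, len(msites), len(csites), len(shared)),
                )
            )
    return pairs


def pairs_to_frame(pairs: Sequence[CeRNAPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "circ_id": p.circ_id,
                "mrna_id": p.mrna_id,
                "M_T": p.M_T,
                "m_p": p.m_p,
                "m_n": p.m_n,
                "m_c": p.m_c,
                "shared_mirnas": ",".join(p.shared_mirnas),
                "cerna_score": p.cerna_score,
                "p_value": p.p_value,
            }
            for p in pairs
        ],
        columns=["circ_id", "mrna_id", "M_T", "m_p", "m_n", "m_c",
                 "shared_mirnas", "cerna_score", "p_value"],
    )


def filter_pairs(
    frame: pd.DataFrame, thresholds: NetworkThresholds | None = None
) -> pd.DataFrame:
    """Apply the retention rule and ranking to a scored pair table.

    Pairs with fewer than ``min_shared`` shared miRNAs or p-value above
    ``max_p`` are dropped (both boundaries kept); survivors are ranked by
    score desc, shared-miRNA count desc, then pair id.
    """
    thresholds = thresholds or NetworkThresholds()
    if thresholds.adjust_p and len(frame):
        from statsmodels.stats.multitest import multipletests

        frame = frame.assign(
            p_value=multipletests(frame["p_value"], method="fdr_bh")[1]
        )
    kept = frame[
        (frame["m_c"] >= thresholds.min_shared)
        & (frame["p_value"] <= thresholds.max_p)
    ].copy()
    return kept.sort_values(
        by=["cerna_score", "m_c", "circ_id", "mrna_id"],
        ascending=[False, False, True, True],
    ).reset_index(drop=True)


def build_network(
    mre_table: pd.DataFrame,
    thresholds: NetworkThresholds | None = None,
    M_T: int | None = None,
) -> tuple[nx.Graph, pd.DataFrame]:
    """Filtered, ranked ceRNA network.

    Returns (graph, ranked pair table). The graph holds typed nodes
    (circRNA/miRNA/mRNA), circRNA-miRNA and miRNA-mRNA targeting edges
    restricted to retained pairs and their shared miRNAs, and scored
    circRNA-mRNA ceRNA edges. Edge set and table rows coincide; there
    are no orphan nodes.
    """
    thresholds = thresholds or NetworkThresholds()
    pairs = score_pairs(mre_table, M_T=M_T)
    kept = filter_pairs(pairs_to_frame(pairs), thresholds)

    graph = nx.Graph()
    for row in kept.itertuples(index=False):
        graph.add_node(row.circ_id, node_type="circRNA")
        graph.add_node(row.mrna_id, node_type="mRNA")
        graph.add_edge(
            row.circ_id,
            row.mrna_id,
            edge_type="ceRNA",
            cerna_score=float(row.cerna_score),
            p_value=float(row.p_value),
            shared_mirnas=row.shared_mirnas,
        )
        for mirna in row.shared_mirnas.split(","):
            graph.add_node(mirna, node_type="miRNA")
            graph.add_edge(row.circ_id, mirna, edge_type="targeting")
            graph.add_edge(mirna, row.mrna_id, edge_type="targeting")
    if mre_table[mre_table["rna_class"] == "mRNA"].empty:
        import warnings

        warnings.warn("MRE table holds no mRNA rows; network is empty")
    return graph, kept
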