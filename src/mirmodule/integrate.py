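"""miRNA/mRNA module integration, hub ranking and enrichment.

A module is one (differentially expressed miRNA, predicted target gene)
pair labelled by the pair of DE statuses.  Inverse modules (miRNA up
with target down, or the reverse) are the expected signature of
cleavage-mode plant miRNA regulation.  Hub miRNAs are ranked by their
number of inverse modules in the bipartite miRNA-gene network, and
target sets can be tested for term enrichment against a user-supplied
flat gene-to-term map with the hypergeometric upper tail.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from mirmodule.quant_de import ExpressionRecord
from mirmodule.target_predict import TargetSite

RELATIONS = ["up-down", "down-up", "up-up", "down-down", "de-unDE"]


@dataclass(frozen=True)
class Module:
    """One DE-miRNA / target-gene pair with its relation label."""

    mirna_id: str
    gene_id: str
    mirna_status: str  # up or down (modules are built from DE miRNAs only)
    gene_status: str  # up, down or unDE
    relation: str
    inverse: bool


@dataclass
class HubScore:
    mirna_id: str
    n_targets: int
    n_de_targets: int
    n_inverse: int


@dataclass
class EnrichmentResult:
    term_id: str
    term_name: str
    k: int  # targets annotated with the term
    K: int  # background genes with the term
    n: int  # target-set size
    N: int  # background size
    p: float
    fdr: float = 1.0


def summarize_percentages(numerator: int, denominator: int) -> float:
    """Percentage of *numerator* in *denominator*, rounded to 2 decimals."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    return round(100.0 * numerator / denominator, 2)


def _relation(mirna_status: str, gene_status: str) -> tuple[str, bool]:
    if gene_status == "unDE":
        return "de-unDE", False
    relation = f"{mirna_status}-{gene_status}"
    return relation, relation in ("up-down", "down-up")


def pair_modules(
    de_mirnas: Iterable[ExpressionRecord],
    sites: Iterable[TargetSite],
    gene_de: Mapping[str, str],
) -> tuple[list[Module], dict[str, object]]:
    """Join DE miRNAs, target sites and gene DE status into modules.

    One module per distinct (DE miRNA, target gene) pair; duplicate
    pairs from multiple sites collapse.  Genes missing from *gene_de*
    are carried as unDE and counted in the summary's warning counter.
    The summary reports counts and percentages per relation class and
    the overall inverse fraction.
    """
    status_of = {r.mirna_id: r.status for r in de_mirnas if r.status in ("up", "down")}
    pairs = sorted(
        {(s.mirna_id, s.transcript_id) for s in sites if s.mirna_id in status_of}
    )
    modules: list[Module] = []
    unresolved = 0
    for mirna_id, gene_id in pairs:
        if gene_id in gene_de:
            gene_status = gene_de[gene_id]
        else:
            gene_status = "unDE"
            unresolved += 1
        relation, inverse = _relation(status_of[mirna_id], gene_status)
        modules.append(
            Module(
                mirna_id=mirna_id,
                gene_id=gene_id,
                mirna_status=status_of[mirna_id],
                gene_status=gene_status,
                relation=relation,
                inverse=inverse,
            )
        )
    total = len(modules)
    by_relation = {rel: sum(1 for m in modules if m.relation == rel) for rel in RELATIONS}
    n_inverse = sum(1 for m in modules if m.inverse)
    summary: dict[str, object] = {
        "n_modules": total,
        "n_inverse": n_inverse,
        "inverse_pct": summarize_percentages(n_inverse, total) if total else 0.0,
        "unresolved_genes": unresolved,
        "by_relation": by_relation,
        "relation_pct": {
            rel: (summarize_percentages(c, total) if total else 0.0)
            for rel, c in by_relation.items()
        },
    }
    return modules, summary


def rank_hubs(modules: Sequence[Module]) -> list[HubScore]:
    """Rank miRNAs by inverse-module degree in the bipartite network.

    Descending by number of inverse modules, then by number of DE
    targets, then lexicographic id.
    """
    scores: dict[str, HubScore] = {}
    for m in modules:
        hs = scores.setdefault(m.mirna_id, HubScore(m.mirna_id, 0, 0, 0))
        hs.n_targets += 1
        if m.gene_status != "unDE":
            hs.n_de_targets += 1
        if m.inverse:
            hs.n_inverse += 1
    return sorted(
        scores.values(), key=lambda h: (-h.n_inverse, -h.n_de_targets, h.mirna_id)
    )


def modules_graph(modules: Sequence[Module]) -> nx.Graph:
    """Bipartite miRNA-gene graph with relation attributes on edges."""
    g = nx.Graph()
    for m in modules:
        g.add_node(m.mirna_id, kind="miRNA", status=m.mirna_status)
        g.add_node(m.gene_id, kind="gene", status=m.gene_status)
        g.add_edge(m.mirna_id, m.gene_id, relation=m.relation, inverse=m.inverse)
    return g


def export_graph(modules: Sequence[Module], graphml_path: str | Path, edges_path: str | Path) -> None:
    nx.write_graphml(modules_graph(modules), str(graphml_path))
    modules_table(modules).to_csv(edges_path, sep="\t", index=False)


def enrich(
    target_genes: Iterable[str],
    background_genes: Iterable[str],
    term_map: Mapping[str, tuple[str, set[str]]] | pd.DataFrame,
) -> list[EnrichmentResult]:
    """Hypergeometric term enrichment of a target set against a background.

    *term_map* maps ``term_id -> (term_name, genes)``, or is a DataFrame
    with ``gene_id``, ``term_id`` and optional ``term_name`` columns.
    The p-value per term is the upper tail P(X >= k) of drawing the
    target set from the background; BH FDR is applied across terms.
    Terms with no background gene are skipped.
    """
    if isinstance(term_map, pd.DataFrame):
        term_map = _terms_from_frame(term_map)
    targets = set(target_genes)
    background = set(background_genes)
    if not targets <= background:
        raise ValueError("target genes must be a subset of the background")
    n, N = len(targets), len(background)
    results: list[EnrichmentResult] = []
    for term_id in sorted(term_map):
        term_name, genes = term_map[term_id]
        term_genes = set(genes) & background
        K = len(term_genes)
        if K == 0:
            continue
        k = len(term_genes & targets)
        p = float(sps.hypergeom.sf(k - 1, N, K, n))
        results.append(EnrichmentResult(term_id, term_name, k, K, n, N, p))
    if results:
        fdrs = multipletests([r.p for r in results], method="fdr_bh")[1]
        for r, fdr in zip(results, fdrs):
            r.fdr = float(fdr)
    return results


def _terms_from_frame(df: pd.DataFrame) -> dict[str, tuple[str, set[str]]]:
    out: dict[str, tuple[str, set[str]]] = {}
    has_name = "term_name" in df.columns
    for row in df.itertuples(index=False):
        term_id = getattr(row, "term_id")
        name = getattr(row, "term_name") if has_name else term_id
        entry = out.setdefault(term_id, (name, set()))
        entry[1].add(getattr(row, "gene_id"))
    return out


def read_gene_de(path: str | Path) -> dict[str, str]:
    """Load a gene DE table (TSV with gene_id and status columns)."""
    df = pd.read_csv(path, sep="\t")
    if df["gene_id"].duplicated().any():
        raise ValueError("duplicate gene ids in DE table")
    return dict(zip(df["gene_id"], df["status"]))


def modules_table(modules: Iterable[Module]) -> pd.DataFrame:
    cols = ["mirna_id", "gene_id", "mirna_status", "gene_status", "relation", "inverse"]
    return pd.DataFrame([{c: getattr(m, c) for c in cols} for m in modules], columns=cols)


def hubs_table(hubs: Iterable[HubScore]) -> pd.DataFrame:
    cols = ["mirna_id", "n_targets", "n_de_targets", "n_inverse"]
    return pd.DataFrame([{c: getattr(h, c) for c in cols} for h in hubs], columns=cols)


def enrichment_table(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    cols = ["term_id", "term_name", "k", "K", "n", "N", "p", "fdr"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
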