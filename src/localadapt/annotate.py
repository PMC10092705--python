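"""Gene assignment of candidate loci and generic term enrichment.

Loci are assigned to a gene when they fall inside its bounds (classified as
exonic or intronic from the gene's exon features) or when the gap to the
nearest gene is strictly below a window (default 5 kb), in which case the
locus is labelled upstream or downstream relative to the gene's strand.
Everything else is intergenic.  Coordinates follow GFF3: 1-based, inclusive;
locus positions are 1-based points.

Term enrichment is a hypergeometric upper-tail test of candidate-gene
overrepresentation per term, with Benjamini-Hochberg FDR across terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import parse_locus_id

__all__ = ["GeneTable", "read_gff_genes", "assign_genes", "term_enrichment"]


@dataclass
class GeneTable:
    """Gene coordinates plus exon intervals, from a GFF3 file."""

    genes: pd.DataFrame                       # id-indexed: contig,start,end,strand
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self):
        bad = self.genes[self.genes["start"] > self.genes["end"]]
        if len(bad):
            raise ValueError(f"gene {bad.index[0]!r} has start > end")
        for gid, spans in self.exons.items():
            g = self.genes.loc[gid]
            for s, e in spans:
                if s > e or s < g["start"] or e > g["end"]:
                    raise ValueError(
                        f"exon ({s}, {e}) of gene {gid!r} not nested in gene bounds")


def read_gff_genes(path) -> GeneTable:
    """Load gene and exon features from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows, exons = [], {}
    for g in db.features_of_type("gene"):
        rows.append({"gene": g.id, "contig": g.seqid, "start": g.start,
                     "end": g.end, "strand": g.strand})
        spans = [(e.start, e.end) for e in db.children(g, featuretype="exon")]
        if spans:
            exons[g.id] = sorted(spans)
    if not rows:
        raise ValueError(f"no gene features in {path}")
    genes = pd.DataFrame(rows).set_index("gene")
    return GeneTable(genes=genes, exons=exons)


def _classify_inside(pos: int, gid: str, table: GeneTable) -> str:
    spans = table.exons.get(gid)
    if not spans:
        return "within-gene-exon"  # no exon annotation: treat gene body as exonic
    for s, e in spans:
        if s <= pos <= e:
            return "within-gene-exon"
    return "within-gene-intron"


def assign_genes(loci, genes: GeneTable, window: int = 5000) -> pd.DataFrame:
    """Assign each locus to a gene by containment or strict <``window`` gap.

    ``loci`` is an iterable of ``"contig:pos"`` ids.  Returns a frame
    indexed by locus with columns ``gene``, ``category``, ``distance``,
    ``tie`` (equidistant flanking genes, broken by lower gene start).
    """
    by_contig = {c: sub.sort_values("start")
                 for c, sub in genes.genes.groupby("contig")}
    rows = []
    for locus in loci:
        contig, pos = parse_locus_id(locus)
        sub = by_contig.get(contig)
        rec = {"locus": locus, "gene": None, "category": "intergenic",
               "distance": np.nan, "tie": False}
        if sub is not None:
            inside = sub[(sub["start"] <= pos) & (pos <= sub["end"])]
            if len(inside):
                gid = inside.index[inside["start"].argmin()]
                rec.update(gene=gid, distance=0,
                           category=_classify_inside(pos, gid, genes))
            else:
                gap = np.where(pos < sub["start"], sub["start"] - pos,
                               pos - sub["end"])
                best = int(gap.min())
                if best < window:
                    hits = sub.index[gap == best]
                    tie = len(hits) > 1
                    gid = sub.loc[hits, "start"].idxmin() if tie else hits[0]
                    g = sub.loc[gid]
                    before = pos < g["start"]
                    if g["strand"] == "-":
                        category = "upstream" if not before else "downstream"
                    else:
                        category = "upstream" if before else "downstream"
                    rec.update(gene=gid, distance=best, category=category, tie=tie)
        rows.append(rec)
    return pd.DataFrame(rows).set_index("locus")


def term_enrichment(candidate_genes, background_genes, term_map) -> pd.DataFrame:
    """Hypergeometric overrepresentation of terms among candidate genes.

    ``term_map`` maps gene id -> term id(s); a two-column DataFrame
    (gene, term) is also accepted.  Candidates must be a subset of the
    background.  Returns per-term counts, the upper-tail p-value and the
    Benjamini-Hochberg FDR.
    """
    candidates = set(candidate_genes)
    background = set(background_genes)
    if not candidates:
        raise ValueError("empty candidate set")
    if not candidates <= background:
        raise ValueError("candidates must be a subset of the background")
    if isinstance(term_map, pd.DataFrame):
        pairs = term_map.iloc[:, :2].itertuples(index=False)
    else:
        pairs = ((g, t) for g, ts in dict(term_map).items()
                 for t in (ts if isinstance(ts, (list, tuple, set)) else [ts]))
    term_genes: dict[str, set] = {}
    for gene, term in pairs:
        if gene in background:
            term_genes.setdefault(term, set()).add(gene)

    M, n = len(background), len(candidates)
    rows = []
    for term, members in sorted(term_genes.items()):
        K = len(members)
        k = len(members & candidates)
        p = float(stats.hypergeom.sf(k - 1, M, K, n)) if k else 1.0
        rows.append({"term": term, "candidates_with_term": k,
                     "background_with_term": K, "p_value": p})
    out = pd.DataFrame(rows).set_index("term")
    if len(out):
        out["fdr"] = multipletests(out["p_value"], method="fdr_bh")[1]
        out = out.sort_values("p_value")
    return out
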