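"""Cross-omics integration: set overlaps, mRNA-protein correlation, and
hypergeometric term enrichment.

Enrichment replaces an external annotation web service with an explicit
upper-tail hypergeometric test against a stated background universe
(the expressed/detected identifiers), with Benjamini-Hochberg q-values
reported alongside the raw p used for the significance call.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InputError


def overlap_analysis(
    sets: Mapping[str, Iterable[str]], universe: Iterable[str] | None = None
) -> dict:
    """Exact Venn-region and pairwise overlap counts for named sets.

    Returns a dict with ``regions`` (exclusive-region counts keyed by the
    frozenset of member set names), ``pairwise`` (intersection / union /
    Jaccard per pair) and ``union`` (total distinct identifiers).  If a
    universe is supplied, identifiers outside it raise an error
    (namespace mismatch guard).
    """
    named = {name: set(s) for name, s in sets.items()}
    if universe is not None:
        uni = set(universe)
        for name, s in named.items():
            stray = s - uni
            if stray:
                raise InputError(
                    f"set {name!r} has {len(stray)} identifiers outside the universe"
                )
    union: set[str] = set().union(*named.values()) if named else set()
    regions: dict[frozenset, int] = {}
    for item in union:
        key = frozenset(name for name, s in named.items() if item in s)
        regions[key] = regions.get(key, 0) + 1
    names = sorted(named)
    pair_rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            inter = len(named[a] & named[b])
            uni_ab = len(named[a] | named[b])
            pair_rows.append((a, b, inter, uni_ab, inter / uni_ab if uni_ab else 0.0))
    pairwise = pd.DataFrame(pair_rows,
                            columns=["set_a", "set_b", "intersection", "union", "jaccard"])
    return {"regions": regions, "pairwise": pairwise, "union": len(union)}


def protein_abundance(
    peptide_log2: pd.DataFrame,
    peptide_meta: pd.DataFrame,
    design: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Protein x sample log2 abundance from proteotypic peptides.

    Per sample, a protein's abundance is the log2 of the summed linear
    intensities of its proteotypic peptides (missing peptide cells
    contribute nothing; a protein with no observed peptide in a sample
    stays missing).  With a run-level design the technical-replicate
    columns are averaged (log2 scale) into one column per mouse.
    """
    meta = peptide_meta.set_index("peptide_seq") if "peptide_seq" in peptide_meta.columns else peptide_meta
    linear = 2.0 ** peptide_log2
    groups: dict[str, list] = {}
    for seq in peptide_log2.index:
        if seq not in meta.index or not bool(meta.at[seq, "proteotypic"]):
            continue
        prots = meta.at[seq, "protein_ids"]
        if len(prots) != 1:
            continue
        groups.setdefault(prots[0], []).append(seq)
    rows = {}
    for protein, seqs in groups.items():
        s = linear.loc[seqs].sum(axis=0, min_count=1)
        rows[protein] = np.log2(s)
    out = pd.DataFrame.from_dict(rows, orient="index", columns=peptide_log2.columns)
    out = out.sort_index()
    out.index.name = "protein_id"
    if design is not None:
        d = design.set_index("run_id") if "run_id" in design.columns else design
        bio = d.loc[out.columns, "bio_rep"]
        out = out.T.groupby(bio).mean().T
        out.columns.name = None
    return out


def mrna_protein_correlation(
    expression: pd.DataFrame,
    protein_log2: pd.DataFrame,
    mapping: pd.DataFrame,
    expression_is_log2: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Per-gene Spearman correlation between mRNA and protein abundance.

    ``mapping`` is a two-column frame (gene_id, protein_id); unmapped
    identifiers are dropped and counted.  Genes whose mRNA or protein
    vector is constant (or incomplete below 3 shared samples) have an
    undefined rho: excluded from the mean, counted in the summary.
    """
    shared_samples = [c for c in expression.columns if c in protein_log2.columns]
    if len(shared_samples) < 3:
        raise InputError("need >= 3 shared samples for rank correlation")
    expr = expression[shared_samples]
    if not expression_is_log2:
        expr = np.log2(expr)
    prot = protein_log2[shared_samples]

    pairs = mapping[["gene_id", "protein_id"]].dropna()
    n_unmapped = 0
    rows = []
    for gene, protein in zip(pairs["gene_id"], pairs["protein_id"]):
        if gene not in expr.index or protein not in prot.index:
            n_unmapped += 1
            continue
        x = expr.loc[gene].to_numpy(dtype=float)
        y = prot.loc[protein].to_numpy(dtype=float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() < 3 or np.ptp(x[ok]) == 0 or np.ptp(y[ok]) == 0:
            rows.append((gene, protein, np.nan))
            continue
        rho = stats.spearmanr(x[ok], y[ok]).statistic
        rows.append((gene, protein, float(rho)))
    per_gene = pd.DataFrame(rows, columns=["gene_id", "protein_id", "spearman_rho"])
    defined = per_gene["spearman_rho"].dropna()
    summary = {
        "mean_rho": float(defined.mean()) if len(defined) else np.nan,
        "n_pairs": int(len(per_gene)),
        "n_undefined": int(per_gene["spearman_rho"].isna().sum()),
        "n_unmapped": n_unmapped,
    }
    return per_gene, summary


def enrich_terms(
    query: Iterable[str],
    background: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of a query set per term.

    p = P(X >= overlap) with X ~ Hypergeom(N=|background|, K=|term in
    background|, n=|query|).  Terms with no background member are
    skipped; BH q-values are reported but the significance flag uses the
    raw p (< alpha), matching how the thresholds are applied downstream.
    """
    query = set(query)
    background = set(background)
    if not query:
        raise InputError("empty query set")
    if not query <= background:
        raise InputError("query must be a subset of the background")
    n = len(query)
    N = len(background)
    rows = []
    for term in sorted(annotation):
        members = set(annotation[term]) & background
        K = len(members)
        if K == 0:
            continue
        overlap = len(query & members)
        p = float(stats.hypergeom.sf(overlap - 1, N, K, n))
        rows.append((term, K, n, overlap, min(p, 1.0)))
    out = pd.DataFrame(rows, columns=["term", "term_size", "query_size", "overlap", "p_value"])
    if len(out):
        out["q_value"] = stats.false_discovery_control(out["p_value"], method="bh")
        out["significant"] = out["p_value"] < alpha
        out = out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out
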