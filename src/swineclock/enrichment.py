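"""Hypergeometric enrichment of probe sets, GWAS-gene overlap, and
random-forest cohort classifiers.

Enrichment: for a foreground probe set of size n drawn from a background of
size N, and a term (e.g. a transcription-factor motif) hitting K background
probes of which k are in the foreground, the enrichment p-value is the
upper hypergeometric tail P(X >= k). No CG-content correction is applied.

GWAS overlap is a symbol-based (case-insensitive) set operation between
EWAS-implicated genes and an external (gene, snp, p) summary table.

The cohort classifiers are bagged decision-tree ensembles (random forests,
500 trees, sqrt(p) features per split) whose accuracy is measured by the
out-of-bag (OOB) error: the fraction of samples misclassified by the trees
that did not see them during bootstrap training.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier

from .core_io import MethylationDataset

__all__ = ["hypergeom_enrich", "overlap_with_gwas", "oob_classify"]


def hypergeom_enrich(
    foreground: set,
    background: set,
    hits: dict[str, set],
    min_k: int = 1,
) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of ``foreground`` per term.

    ``hits`` maps term id -> probe set (intersected with the background).
    Terms with fewer than ``min_k`` foreground hits are dropped. Returns a
    DataFrame sorted by p with columns ``term, k, K, n, N, p_hyper, fold``.
    """
    foreground = set(foreground)
    background = set(background)
    if not foreground <= background:
        raise ValueError("foreground must be a subset of background")
    N = len(background)
    n = len(foreground)
    rows = []
    for term, probes in hits.items():
        term_bg = set(probes) & background
        K = len(term_bg)
        k = len(term_bg & foreground)
        if k < min_k:
            continue
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        fold = (k / n) / (K / N) if n and K else np.nan
        rows.append(
            {"term": term, "k": k, "K": K, "n": n, "N": N, "p_hyper": min(p, 1.0), "fold": fold}
        )
    out = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p_hyper", "fold"])
    return out.sort_values(["p_hyper", "term"], kind="mergesort").reset_index(drop=True)


def overlap_with_gwas(
    ewas_genes: dict[str, set], gwas_table: pd.DataFrame
) -> pd.DataFrame:
    """Overlap EWAS-implicated genes with a GWAS (gene, snp, p) table.

    ``ewas_genes`` maps analysis name (e.g. age / minipig / interaction) to
    a gene-symbol set. Matching is case-insensitive. Returns one row per
    overlapping gene with a boolean membership flag per analysis and the
    gene's top SNP (smallest GWAS p).
    """
    if gwas_table.empty:
        raise ValueError("empty GWAS table")
    tab = gwas_table.copy()
    tab["_gene_key"] = tab["gene"].astype(str).str.casefold()
    sets_cf = {name: {g.casefold() for g in genes} for name, genes in ewas_genes.items()}
    all_ewas = set().union(*sets_cf.values()) if sets_cf else set()
    tab = tab[tab["_gene_key"].isin(all_ewas)]
    rows = []
    for key, grp in tab.groupby("_gene_key"):
        top = grp.loc[grp["p"].idxmin()]
        row = {
            "gene": top["gene"],
            "top_snp": top["snp"],
            "gwas_p": float(top["p"]),
            "n_snps": len(grp),
        }
        for name in ewas_genes:
            row[f"in_{name}"] = key in sets_cf[name]
        rows.append(row)
    cols = ["gene", "top_snp", "gwas_p", "n_snps"] + [f"in_{n}" for n in ewas_genes]
    out = pd.DataFrame(rows, columns=cols)
    return out.sort_values("gwas_p", kind="mergesort").reset_index(drop=True)


def oob_classify(
    ds: MethylationDataset,
    label: str,
    n_trees: int = 500,
    seed: int = 0,
) -> tuple[float, pd.DataFrame]:
    """Random-forest classification of a sample label with OOB accuracy.

    ``label`` is one of the sample-sheet columns (breed, tissue, sex, ...).
    Returns ``(oob_error, confusion)`` where the confusion table rows are
    true classes and columns OOB-predicted classes. Deterministic given
    ``seed``.
    """
    if label not in ds.samples.columns:
        raise ValueError(f"unknown label column {label!r}")
    y = ds.samples[label].astype(str).to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"label {label!r} has a single class")
    if counts.min() < 3:
        raise ValueError(f"need >= 3 samples per class, got {dict(zip(classes, counts))}")
    X = ds.betas.to_numpy(float).T
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        bootstrap=True,
        random_state=seed,
        n_jobs=1,
    )
    rf.fit(X, y)
    votes = rf.oob_decision_function_
    # samples never out-of-bag (vanishingly rare at 500 trees) count as errors
    has_votes = votes.sum(axis=1) > 0
    pred = np.array(rf.classes_)[np.argmax(votes, axis=1)]
    correct = (pred == y) & has_votes
    oob_error = float(1.0 - correct.mean())
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(pred, name="oob_pred"), dropna=False
    )
    confusion = confusion.reindex(index=classes, columns=classes, fill_value=0)
    return oob_error, confusion
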