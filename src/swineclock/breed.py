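"""Breed-comparison EWAS: per-CpG multivariate models contrasting two pig
breeds (domestic as reference).

Two ordinary-least-squares models are fitted per CpG:

* model 1: beta ~ age + breed — the age coefficient identifies CpGs aging
  in both breeds (shared aging), the breed indicator identifies baseline
  methylation differences;
* model 2: beta ~ age + breed + age x breed — the interaction coefficient
  identifies CpGs whose *rate* of methylation change differs between
  breeds, regardless of direction.

Coefficient Z statistics use the normal approximation (exact Student t by
flag); interaction p-values are Benjamini-Hochberg adjusted, and each
5%-FDR interaction CpG is placed in one of eight sign categories from the
per-breed aging Z statistics (hyper/hypo/ns in each breed, the doubly-ns
cell excluded).
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import MethylationDataset
from .ewas import P_FLOOR, _z_from_p, screen_age

__all__ = [
    "fit_breed_models",
    "call_significant",
    "categorize_interactions",
    "REFERENCE_BREED",
]

REFERENCE_BREED = "domestic"

#: Z bin edge for the 8-way interaction categories (|z| > 1.96 = nominal 5%).
Z_EDGE = 1.96


def _ols_all_probes(X: np.ndarray, Y: np.ndarray):
    """OLS of every probe (columns of Y) on design X; returns (coef, se).

    coef, se have shape (n_coef, n_probes). Requires full-rank X.
    """
    n, q = X.shape
    XtX = X.T @ X
    if np.linalg.matrix_rank(XtX) < q:
        raise ValueError("rank-deficient design (e.g. constant age within a breed)")
    XtX_inv = np.linalg.inv(XtX)
    B = XtX_inv @ (X.T @ Y)
    resid = Y - X @ B
    dof = max(n - q, 1)
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(np.outer(np.diag(XtX_inv), sigma2))
    return B, se, dof


def fit_breed_models(ds: MethylationDataset, exact_t: bool = False) -> pd.DataFrame:
    """Fit both breed-contrast models for every probe.

    The dataset must contain exactly two breed labels, one of them the
    reference (``domestic`` if present, else the lexicographically first),
    with at least 4 samples per breed. Missing betas are dropped per probe.

    Returns a DataFrame indexed by probe id with model-1 columns
    (``age_coef/z/p``, ``breed_coef/z/p``), model-2 interaction columns
    (``inter_coef/z/p/q``), per-breed aging Z (``z_domestic, z_minipig``
    named after the actual labels via attrs), and a ``category`` column
    (filled by :func:`categorize_interactions` for 5%-FDR interactions).
    """
    breeds = sorted(ds.samples["breed"].unique())
    if len(breeds) != 2:
        raise ValueError(f"need exactly 2 breed labels, got {breeds}")
    ref = REFERENCE_BREED if REFERENCE_BREED in breeds else breeds[0]
    other = [b for b in breeds if b != ref][0]
    counts = ds.samples["breed"].value_counts()
    if counts.min() < 4:
        raise ValueError(f"need >= 4 samples per breed, got {counts.to_dict()}")

    age = ds.samples["age_years"].to_numpy(float)
    ind = (ds.samples["breed"] == other).to_numpy(float)
    Y = ds.betas.to_numpy(float).T  # samples x probes
    X1 = np.column_stack([np.ones_like(age), age, ind])
    X2 = np.column_stack([np.ones_like(age), age, ind, age * ind])

    def fit(X, Yc):
        B, se, dof = _ols_all_probes(X, Yc)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = np.where(se > 0, B / se, 0.0)
        return B, z, dof

    nan_mask = np.isnan(Y)
    if nan_mask.any():
        # per-probe complete-case fits for probes with missing values
        complete = ~nan_mask.any(axis=0)
        out = np.full((7, Y.shape[1]), np.nan)
        if complete.any():
            B1, z1, dof1 = fit(X1, Y[:, complete])
            B2, z2, dof2 = fit(X2, Y[:, complete])
            out[0, complete], out[1, complete] = B1[1], z1[1]
            out[2, complete], out[3, complete] = B1[2], z1[2]
            out[4, complete], out[5, complete] = B2[3], z2[3]
            out[6, complete] = dof1
        for j in np.flatnonzero(~complete):
            keep = ~nan_mask[:, j]
            if keep.sum() < X2.shape[1] + 1:
                continue
            B1, z1, dof1 = fit(X1[keep], Y[keep, j : j + 1])
            B2, z2, dof2 = fit(X2[keep], Y[keep, j : j + 1])
            out[:, j] = [B1[1, 0], z1[1, 0], B1[2, 0], z1[2, 0], B2[3, 0], z2[3, 0], dof1]
        age_coef, age_z, breed_coef, breed_z, inter_coef, inter_z, dofs = out
        dof1 = dofs
        dof2 = dofs - 1
    else:
        B1, z1, dof1 = fit(X1, Y)
        B2, z2, dof2 = fit(X2, Y)
        age_coef, age_z = B1[1], z1[1]
        breed_coef, breed_z = B1[2], z1[2]
        inter_coef, inter_z = B2[3], z2[3]

    def pvals(z, dof):
        if exact_t:
            p = 2.0 * stats.t.sf(np.abs(z), dof)
        else:
            p = 2.0 * stats.norm.sf(np.abs(z))
        return np.minimum(np.maximum(p, P_FLOOR), 1.0)

    age_p = pvals(age_z, dof1)
    breed_p = pvals(breed_z, dof1)
    inter_p = pvals(inter_z, dof2)
    inter_q = multipletests(inter_p, method="fdr_bh")[1]

    # per-breed aging Z from breed-stratified correlation screens
    z_by_breed = {}
    for b in (ref, other):
        sub = ds.subset_samples(ds.samples.index[ds.samples["breed"] == b])
        z_by_breed[b] = screen_age(sub, None)["z"]

    rec = pd.DataFrame(
        {
            "age_coef": age_coef,
            "age_z": age_z,
            "age_p": age_p,
            "breed_coef": breed_coef,
            "breed_z": breed_z,
            "breed_p": breed_p,
            "inter_coef": inter_coef,
            "inter_z": inter_z,
            "inter_p": inter_p,
            "inter_q": inter_q,
            "z_domestic": z_by_breed[ref].to_numpy(),
            "z_minipig": z_by_breed[other].to_numpy(),
        },
        index=ds.betas.index,
    )
    rec.attrs["reference_breed"] = ref
    rec.attrs["other_breed"] = other
    rec["category"] = categorize_interactions(rec)
    return rec


def call_significant(
    records: pd.DataFrame, main_cut: float = 1e-8, inter_fdr: float = 0.05
) -> dict[str, set]:
    """Significant probe sets: shared-aging (age_p < main_cut), breed
    baseline (breed_p < main_cut), interaction (BH q < inter_fdr)."""
    return {
        "shared_aging": set(records.index[records["age_p"] < main_cut]),
        "breed_baseline": set(records.index[records["breed_p"] < main_cut]),
        "interaction": set(records.index[records["inter_q"] < inter_fdr]),
    }


def _bin(z: float, edge: float) -> str:
    if z > edge:
        return "hyper"
    if z < -edge:
        return "hypo"
    return "ns"


def categorize_interactions(
    records: pd.DataFrame, inter_fdr: float = 0.05, z_edge: float = Z_EDGE
) -> pd.Series:
    """8-way sign categories for significant-interaction CpGs.

    Each breed's aging Z is binned into hyper (z > +z_edge), hypo
    (z < -z_edge), or ns; the 3x3 grid minus the (ns, ns) cell gives eight
    categories like ``hypo-domestic/hyper-minipig``; doubly-ns probes are
    labeled ``discordant-unclassified``. Probes without a significant
    interaction get ``none``.
    """
    out = []
    for pid, row in records.iterrows():
        if not (row["inter_q"] < inter_fdr):
            out.append("none")
            continue
        bd = _bin(row["z_domestic"], z_edge)
        bm = _bin(row["z_minipig"], z_edge)
        if bd == "ns" and bm == "ns":
            out.append("discordant-unclassified")
        else:
            out.append(f"{bd}-domestic/{bm}-minipig")
    return pd.Series(out, index=records.index, name="category")
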