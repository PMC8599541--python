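"""Per-tissue EWAS of chronological age and Stouffer cross-tissue meta-analysis.

Screening is a per-probe Pearson correlation of beta values with age within
one tissue; each probe gets the correlation r, the Student statistic
t = r sqrt(n-2)/sqrt(1-r^2), its two-sided p at n-2 df, and a signed normal
quantile z = sign(r) * Phi^-1(1 - p/2). Signed Z's are combined across
tissues with Stouffer's method, z_meta = sum(w_i z_i) / sqrt(sum(w_i^2)),
unit weights by default (sqrt(n) weighting optional). p-values are floored
at 1e-300 so z stays finite.

Missing betas are dropped pairwise, with the per-probe n recorded.
Zero-variance probes get r = 0, p = 1, z = 0.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import MethylationDataset

__all__ = [
    "screen_age",
    "stouffer_meta",
    "select_top_cpgs",
    "genomic_context_summary",
    "overlap_sets",
]

P_FLOOR = 1e-300

#: TSS-distance bin edges (bp, signed; negative = upstream), spanning the
#: window typically plotted for array probes.
DEFAULT_TSS_BINS = (-np.inf, -10_000, -5_000, -1_000, 0, 1_000, 5_000, 10_000, np.inf)


def _corr_with_age(betas: np.ndarray, age: np.ndarray):
    """Vectorized pairwise-complete Pearson r of each row with age.

    Returns (r, n_used) arrays; zero-variance rows get r = 0.
    """
    mask = ~np.isnan(betas)
    n_used = mask.sum(axis=1)
    a = np.where(mask, betas, 0.0)
    w = mask.astype(float)
    sum_x = a.sum(axis=1)
    sum_x2 = (a * a).sum(axis=1)
    sum_y = w @ age
    sum_y2 = w @ (age * age)
    sum_xy = a @ age
    n = np.maximum(n_used, 1)
    cov = sum_xy - sum_x * sum_y / n
    vx = sum_x2 - sum_x**2 / n
    vy = sum_y2 - sum_y**2 / n
    denom = np.sqrt(np.maximum(vx, 0) * np.maximum(vy, 0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / denom, 0.0)
    return np.clip(r, -1.0, 1.0), n_used


def _z_from_p(p: np.ndarray, sign: np.ndarray) -> np.ndarray:
    p = np.maximum(p, P_FLOOR)
    return sign * stats.norm.isf(p / 2.0)


def _bicor_weights(x: np.ndarray) -> np.ndarray:
    """Tukey biweights around the median (9-MAD window); constant vectors
    fall back to uniform weights."""
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return np.ones_like(x)
    u = (x - med) / (9.0 * mad)
    w = np.where(np.abs(u) < 1, (1 - u**2) ** 2, 0.0)
    return w


def _bicor(x: np.ndarray, y: np.ndarray) -> float:
    """Biweight midcorrelation: a median/MAD-weighted robust correlation."""
    wx, wy = _bicor_weights(x), _bicor_weights(y)
    xs = (x - np.median(x)) * wx
    ys = (y - np.median(y)) * wy
    denom = np.sqrt((xs**2).sum() * (ys**2).sum())
    if denom == 0:
        return 0.0
    return float(np.clip((xs * ys).sum() / denom, -1.0, 1.0))


def screen_age(
    ds: MethylationDataset, tissue: str | None, method: str = "pearson"
) -> pd.DataFrame:
    """EWAS of chronological age within one tissue (or all samples if None).

    Returns a DataFrame with columns ``probe_id, tissue, n, r, t, p, z``.
    ``method`` is ``pearson`` (default) or ``biweight`` (robust biweight
    midcorrelation; the downstream t/p/z machinery is unchanged).
    Requires at least 4 samples.
    """
    if method not in ("pearson", "biweight"):
        raise ValueError(f"unknown correlation method {method!r}")
    if tissue is None:
        sub = ds
        label = "all"
    else:
        keep = ds.samples.index[ds.samples["tissue"] == tissue]
        if len(keep) == 0:
            raise ValueError(f"unknown tissue {tissue!r}")
        sub = ds.subset_samples(keep)
        label = tissue
    if sub.n_samples < 4:
        raise ValueError(f"need >= 4 samples in tissue {label!r}, got {sub.n_samples}")
    age = sub.samples["age_years"].to_numpy(float)
    betas = sub.betas.to_numpy(float)
    if method == "pearson":
        r, n_used = _corr_with_age(betas, age)
    else:
        mask = ~np.isnan(betas)
        n_used = mask.sum(axis=1)
        r = np.array(
            [
                _bicor(row[m], age[m]) if m.sum() >= 3 and row[m].std() > 0 else 0.0
                for row, m in zip(betas, mask)
            ]
        )
    df = np.maximum(n_used - 2, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(np.maximum(1 - r**2, 0))
        t = np.where(np.abs(r) >= 1.0, np.sign(r) * np.inf, t)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(n_used < 3, 1.0, p)
    p = np.minimum(np.maximum(p, P_FLOOR), 1.0)
    degenerate = r == 0
    p = np.where(degenerate, 1.0, p)
    z = _z_from_p(p, np.sign(r))
    return pd.DataFrame(
        {
            "probe_id": sub.betas.index,
            "tissue": label,
            "n": n_used,
            "r": r,
            "t": t,
            "p": p,
            "z": z,
        }
    ).set_index("probe_id")


def stouffer_meta(
    records_by_tissue: dict[str, pd.DataFrame], weights: dict[str, float] | None = None
) -> pd.DataFrame:
    """Combine per-tissue signed Z's across tissues with Stouffer's method.

    ``z_meta = sum(w_i z_i) / sqrt(sum(w_i^2))`` over the tissues in which a
    probe was screened; unit weights unless ``weights`` maps tissue -> w.
    Returns a DataFrame with ``z_meta, p_meta, k`` per probe.
    """
    if not records_by_tissue:
        raise ValueError("no tissue records to combine")
    zw = None
    w2 = None
    k = None
    for tissue, rec in records_by_tissue.items():
        w = 1.0 if weights is None else float(weights[tissue])
        z = rec["z"]
        zw = z * w if zw is None else zw.add(z * w, fill_value=0.0)
        ww = pd.Series(w**2, index=z.index)
        w2 = ww if w2 is None else w2.add(ww, fill_value=0.0)
        kk = pd.Series(1, index=z.index)
        k = kk if k is None else k.add(kk, fill_value=0)
    z_meta = zw / np.sqrt(w2)
    p_meta = np.minimum(np.maximum(2.0 * stats.norm.sf(np.abs(z_meta)), P_FLOOR), 1.0)
    return pd.DataFrame({"z_meta": z_meta, "p_meta": p_meta, "k": k.astype(int)})


def select_top_cpgs(
    records: pd.DataFrame, p_cut: float = 1e-4, cap_per_direction: int = 500
) -> tuple[list[str], list[str]]:
    """Top hyper-/hypomethylating CpGs: among probes with p < p_cut, the
    <= cap probes with largest z and the <= cap with smallest z. Ties break
    by probe id for determinism.

    ``records`` may be a per-tissue screen (columns z, p) or a meta table
    (z_meta, p_meta). Returns (hyper_ids, hypo_ids).
    """
    zcol = "z" if "z" in records.columns else "z_meta"
    pcol = "p" if "p" in records.columns else "p_meta"
    sig = records[records[pcol] < p_cut]
    pos = sig[sig[zcol] > 0]
    neg = sig[sig[zcol] < 0]
    if len(pos):
        pos = pos.iloc[np.lexsort((pos.index.to_numpy(), -pos[zcol].to_numpy()))]
    if len(neg):
        neg = neg.iloc[np.lexsort((neg.index.to_numpy(), neg[zcol].to_numpy()))]
    return (
        pos.index[:cap_per_direction].tolist(),
        neg.index[:cap_per_direction].tolist(),
    )


def genomic_context_summary(
    top_probes,
    annotation: pd.DataFrame,
    background,
    records: pd.DataFrame | None = None,
    tss_bins=DEFAULT_TSS_BINS,
) -> dict[str, pd.DataFrame]:
    """Genomic-context composition of a top-CpG set versus background.

    Returns ``{"tss": ..., "island": ...}``: per-TSS-distance-bin counts and
    proportions for foreground and background, and (when ``records`` is
    given) mean/median association z for island versus non-island probes.
    Probes missing from the annotation are excluded, with the count reported
    in the table attrs.
    """
    fg = pd.Index(top_probes)
    bg = pd.Index(background)
    n_missing = len(fg.difference(annotation.index)) + len(bg.difference(annotation.index))
    fg = fg.intersection(annotation.index)
    bg = bg.intersection(annotation.index)
    bins = np.asarray(tss_bins, float)
    labels = [f"[{bins[i]:g},{bins[i+1]:g})" for i in range(len(bins) - 1)]
    out = {}
    rows = []
    for name, ids in (("foreground", fg), ("background", bg)):
        d = annotation.loc[ids, "dist_to_tss"].to_numpy(float)
        cnt, _ = np.histogram(d, bins=bins)
        total = max(cnt.sum(), 1)
        for lab, c in zip(labels, cnt):
            rows.append({"set": name, "bin": lab, "count": int(c), "proportion": c / total})
    tss = pd.DataFrame(rows)
    tss.attrs["n_missing_annotation"] = n_missing
    out["tss"] = tss

    isl_rows = []
    for name, ids in (("foreground", fg), ("background", bg)):
        isl = annotation.loc[ids, "island"].astype(bool)
        entry = {
            "set": name,
            "n_island": int(isl.sum()),
            "n_non_island": int((~isl).sum()),
            "prop_island": float(isl.mean()) if len(isl) else np.nan,
        }
        if records is not None:
            zcol = "z" if "z" in records.columns else "z_meta"
            z = records[zcol].reindex(ids)
            entry["mean_z_island"] = float(z[isl.to_numpy()].mean())
            entry["mean_z_non_island"] = float(z[~isl.to_numpy()].mean())
            entry["median_z_island"] = float(z[isl.to_numpy()].median())
            entry["median_z_non_island"] = float(z[~isl.to_numpy()].median())
        isl_rows.append(entry)
    out["island"] = pd.DataFrame(isl_rows)
    return out


def overlap_sets(top_sets_by_tissue: dict[str, set]) -> tuple[pd.DataFrame, pd.Series]:
    """Upset-style intersection counts over per-tissue top-CpG sets.

    Returns (table, n_tissues): one row per nonempty membership pattern with
    a boolean column per tissue plus ``count``, and a per-probe Series of
    how many tissues contain it.
    """
    if len(top_sets_by_tissue) < 2:
        raise ValueError("need at least 2 sets for an overlap table")
    tissues = sorted(top_sets_by_tissue)
    union = sorted(set().union(*top_sets_by_tissue.values()))
    membership = {
        p: frozenset(t for t in tissues if p in top_sets_by_tissue[t]) for p in union
    }
    counts: dict[frozenset, int] = {}
    for pat in membership.values():
        counts[pat] = counts.get(pat, 0) + 1
    rows = []
    for pat in sorted(counts, key=lambda s: (len(s), tuple(sorted(s)))):
        row = {t: (t in pat) for t in tissues}
        row["count"] = counts[pat]
        rows.append(row)
    table = pd.DataFrame(rows)
    n_tissues = pd.Series({p: len(m) for p, m in membership.items()}, dtype=int)
    return table, n_tissues
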