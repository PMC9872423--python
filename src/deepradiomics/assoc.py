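"""Radiogenomic association scan: per-(DRF, GF) linear mixed-effect models.

Each image-level radiomic feature X is regressed on a patient-level genomic
feature G with a per-patient random intercept absorbing the correlation
between a patient's repeated images::

    X_ij = beta0 + beta1 * G_i + u_i + e_ij,   u_i ~ N(0, sigma_u^2)

The model is fitted by restricted maximum likelihood.  Because G is
constant within a patient, the REML profile reduces to a one-dimensional
optimization over the variance ratio theta = sigma_u^2 / sigma_e^2, with
the GLS step operating on per-patient means — this makes the mass-
univariate scan (thousands of pairs) fast and exactly vectorizable across
radiomic features.  Two-sided p-values come from the Wald statistic
beta1 / se(beta1) referred to Student's t with Satterthwaite degrees of
freedom (capped at n_patients - 2, since the predictor varies only between
patients), with a Kackar–Harville variance inflation for the estimated
variance ratio; they are Benjamini–Hochberg adjusted within each
genomic-feature category by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .dae import N_KERNELS, DRFMatrix
from .genomics import CATEGORIES, GenomicFeatureTable

__all__ = [
    "LMEPairFit",
    "fit_lme_pair",
    "run_scan",
    "count_per_kernel",
    "top_features",
    "top_gfs",
]

#: columns of an association table
ASSOC_COLUMNS = ("drf_id", "kernel", "gf_id", "gf_category",
                 "beta1", "p", "p_adj", "significant")

_LOG_THETA_GRID = np.concatenate(([-np.inf], np.linspace(-6.0, 8.0, 71)))


@dataclass
class LMEPairFit:
    beta0: float
    beta1: float
    se1: float
    sigma_u: float
    sigma_e: float
    p: float
    n_images: int
    n_patients: int
    method: str = "reml"  # "ols" when the random intercept is degenerate


def _group_stats(y: np.ndarray, pidx: np.ndarray, n_patients: int,
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-patient counts, means, and pooled within-patient SS for columns of y."""
    if y.ndim == 1:
        y = y[:, None]
    counts = np.bincount(pidx, minlength=n_patients).astype(float)
    sums = np.zeros((n_patients, y.shape[1]))
    np.add.at(sums, pidx, y)
    means = sums / counts[:, None]
    ssw = ((y - means[pidx]) ** 2).sum(axis=0)
    return counts, means, ssw


def _profile_reml(g: np.ndarray, counts: np.ndarray, ybar: np.ndarray,
                  ssw: np.ndarray, n_images: int,
                  ) -> tuple[np.ndarray, ...]:
    """Vectorized REML fit of the random-intercept model for many DRF columns.

    Returns beta0, beta1, se1, sigma_u, sigma_e, theta arrays (one entry per
    DRF column in ``ybar``).
    """
    P, D = ybar.shape
    N = n_images
    thetas = np.power(10.0, _LOG_THETA_GRID)
    thetas[0] = 0.0
    crits = np.empty((thetas.size, D))
    cache = []
    for t, theta in enumerate(thetas):
        w = counts / (1.0 + counts * theta)
        S0, S1, S2 = w.sum(), w @ g, w @ (g * g)
        T0 = w @ ybar
        T1 = (w * g) @ ybar
        T2 = w @ (ybar ** 2)
        det = S0 * S2 - S1 * S1
        beta1 = (S0 * T1 - S1 * T0) / det
        beta0 = (T0 - beta1 * S1) / S0
        Q = np.maximum(ssw + T2 - beta0 * T0 - beta1 * T1, 1e-300)
        crits[t] = ((N - 2) * np.log(Q)
                    + np.log1p(counts * theta).sum()
                    + np.log(det))
        cache.append((w, S0, S1, det, beta0, beta1, Q))
    best = crits.argmin(axis=0)

    # local quadratic refinement on log-theta where the minimum is interior
    theta_hat = thetas[best]
    interior = (best > 1) & (best < thetas.size - 1)
    if interior.any():
        ib = best[interior]
        lt = _LOG_THETA_GRID
        c0 = crits[ib - 1, np.flatnonzero(interior)]
        c1 = crits[ib, np.flatnonzero(interior)]
        c2 = crits[ib + 1, np.flatnonzero(interior)]
        denom = c0 - 2 * c1 + c2
        shift = np.where(np.abs(denom) > 1e-12,
                         0.5 * (c0 - c2) / np.where(denom == 0, 1, denom), 0.0)
        shift = np.clip(shift, -1.0, 1.0)
        step = lt[2] - lt[1]
        theta_hat[interior] = 10.0 ** (lt[ib] + shift * step)

    def _eval(theta_vec: np.ndarray):
        # per-column GLS summaries at per-column theta (P x D weights)
        w = counts[:, None] / (1.0 + counts[:, None] * theta_vec[None, :])
        S0 = w.sum(axis=0)
        S1 = g @ w
        S2 = (g * g) @ w
        T0 = (w * ybar).sum(axis=0)
        T1 = (w * g[:, None] * ybar).sum(axis=0)
        T2 = (w * ybar ** 2).sum(axis=0)
        det = S0 * S2 - S1 * S1
        beta1 = (S0 * T1 - S1 * T0) / det
        beta0 = (T0 - beta1 * S1) / S0
        Q = np.maximum(ssw + T2 - beta0 * T0 - beta1 * T1, 1e-300)
        crit = ((N - 2) * np.log(Q)
                + np.log1p(counts[:, None] * theta_vec[None, :]).sum(axis=0)
                + np.log(det))
        return beta0, beta1, Q, det, S0, crit

    beta0, beta1, Q, det, S0, crit0 = _eval(theta_hat)
    sigma_e2 = Q / (N - 2)
    var_plugin = sigma_e2 * S0 / det
    sigma_e = np.sqrt(sigma_e2)
    sigma_u = np.sqrt(theta_hat * sigma_e2)

    # Small-sample corrections.  The plug-in Wald test with a fixed
    # reference df is anti-conservative in the far tail of a mass-
    # univariate scan, because it ignores the sampling variability of the
    # estimated variance ratio.  Two standard remedies are applied:
    #   * Kackar–Harville: inflate Var(beta1) by (d beta1/d theta)^2 *
    #     Var(theta-hat);
    #   * Satterthwaite: per-pair denominator df
    #     2 * Var(beta1)^2 / Var(Var-hat(beta1)), with the covariance of
    #     (theta-hat, sigma_e2-hat) taken from the curvature of the REML
    #     deviance (the criterion above is -2 log restricted likelihood up
    #     to a constant).
    var_adj = var_plugin.copy()
    df = np.full(ybar.shape[1], float(N - 2))
    pos = theta_hat > 0
    if pos.any():
        h = 0.05 * theta_hat
        h[~pos] = 1.0  # unused placeholder
        _, b_p, Q_p, det_p, S0_p, c_p = _eval(theta_hat + h)
        _, b_m, Q_m, det_m, S0_m, c_m = _eval(np.maximum(theta_hat - h, 0.0))
        hp = pos
        hh = h[hp]
        dbeta = (b_p[hp] - b_m[hp]) / (2 * hh)
        curv = (c_p[hp] - 2 * crit0[hp] + c_m[hp]) / hh ** 2
        # a flat profile (e.g. one image per patient) carries no information
        # on theta: the fit is then exactly OLS and keeps df = N - 2
        informative = curv > 1e-6
        var_theta = np.where(informative, 2.0 / np.maximum(curv, 1e-300), 0.0)
        var_adj[hp] = var_plugin[hp] + dbeta ** 2 * var_theta

        # Satterthwaite df from the (theta, sigma_e2) REML information
        f0 = S0 / det
        fprime = (S0_p / det_p - S0_m / det_m)[hp] / (2 * hh)
        qprime = (Q_p - Q_m)[hp] / (2 * hh)
        se2 = sigma_e2[hp]
        h_tt = np.maximum(curv, 1e-300)
        h_ts = -qprime / se2 ** 2
        h_ss = (N - 2) / se2 ** 2
        deth = h_tt * h_ss - h_ts ** 2
        informative &= deth > 0  # non-PD information -> keep OLS reference
        with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
            safe_det = np.where(deth > 0, deth, 1.0)
            v_tt = 2 * h_ss / safe_det
            v_ts = -2 * h_ts / safe_det
            v_ss = 2 * h_tt / safe_det
            g_t = se2 * fprime
            g_s = f0[hp]
            var_of_var = (g_t ** 2 * v_tt + 2 * g_t * g_s * v_ts
                          + g_s ** 2 * v_ss)
            nu = 2.0 * var_plugin[hp] ** 2 / np.maximum(var_of_var, 1e-300)
        df[hp] = np.where(informative, np.clip(nu, 2.0, N - 2), N - 2)
    se1 = np.sqrt(var_adj)
    return beta0, beta1, se1, sigma_u, sigma_e, theta_hat, df


def _wald_p(beta1: np.ndarray, se1: np.ndarray, df: np.ndarray,
            n_patients: int) -> np.ndarray:
    """Two-sided Wald p against Student-t with Satterthwaite df.

    The per-pair df is additionally capped at n_patients - 2: the genomic
    predictor varies only between patients, so the between-patient degrees
    of freedom bound the information (this matches the denominator-df
    convention of nlme for group-level covariates).  A normal reference is
    anti-conservative at cohort sizes around 50-100 patients.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se1 > 0, beta1 / np.where(se1 == 0, 1, se1), 0.0)
    df_eff = np.minimum(np.asarray(df, dtype=float), max(n_patients - 2, 1))
    p = 2.0 * stats.t.sf(np.abs(z), df=df_eff)
    return np.clip(p, np.finfo(float).tiny, 1.0)


def fit_lme_pair(drf_values: Sequence[float],
                 gf_value: Mapping[str, float] | pd.Series,
                 patient_of_image: Sequence[str]) -> LMEPairFit:
    """Fit the random-intercept association model for one (DRF, GF) pair.

    ``drf_values`` are per-image; ``gf_value`` maps patient id to the
    patient-level genomic value, which is replicated across the patient's
    images.
    """
    y = np.asarray(drf_values, dtype=float)
    patients = np.asarray(patient_of_image)
    if y.size != patients.size:
        raise ValueError("drf_values and patient_of_image differ in length")
    gf = pd.Series(gf_value).astype(float)
    uniq, pidx = np.unique(patients, return_inverse=True)
    missing = [p for p in uniq if p not in gf.index]
    if missing:
        raise ValueError(f"images reference patients without a GF value: "
                         f"{missing[:5]}")
    if uniq.size < 3:
        raise ValueError("need at least 3 patients")
    g = gf.loc[uniq].to_numpy()
    if np.ptp(g) == 0:
        raise ValueError("genomic feature is constant (degenerate predictor)")

    counts, ybar, ssw = _group_stats(y, pidx, uniq.size)
    beta0, beta1, se1, sigma_u, sigma_e, theta, df = _profile_reml(
        g, counts, ybar, ssw, y.size)
    p = _wald_p(beta1, se1, df, uniq.size)
    method = "reml" if theta[0] > 0 else "ols"
    return LMEPairFit(beta0=float(beta0[0]), beta1=float(beta1[0]),
                      se1=float(se1[0]), sigma_u=float(sigma_u[0]),
                      sigma_e=float(sigma_e[0]), p=float(p[0]),
                      n_images=int(y.size), n_patients=int(uniq.size),
                      method=method)


def run_scan(drfs: DRFMatrix, gfs: GenomicFeatureTable, alpha: float = 0.05,
             bh_family: str = "category") -> pd.DataFrame:
    """Scan every (DRF, GF) pair; BH-adjust within GF categories.

    Returns a table with one row per pair: slope, raw and adjusted p, and a
    significance flag at adjusted p < alpha.  Genomic features are z-scored
    per column before fitting (slope sign unchanged); DRFs enter as given.
    Deterministic, and invariant to the row order of either input.
    """
    if bh_family not in ("category", "global"):
        raise ValueError("bh_family must be 'category' or 'global'")
    patients_img = drfs.image_index["patient_id"].to_numpy()
    shared = [p for p in gfs.patient_ids if p in set(patients_img)]
    if not shared:
        raise ValueError("no overlapping patients between DRFs and GFs")
    keep = np.isin(patients_img, shared)
    y = drfs.values[keep]
    pat = patients_img[keep]
    # canonical patient order -> scan output independent of input row order
    order = np.argsort(drfs.image_index["image_id"].to_numpy()[keep])
    y, pat = y[order], pat[order]
    uniq, pidx = np.unique(pat, return_inverse=True)
    counts, ybar, ssw = _group_stats(y, pidx, uniq.size)

    kernel_of = drfs.kernel_map.set_index("feature_id")["kernel"].to_dict()
    rows = []
    for gf_id in gfs.values.columns:
        gcol = gfs.values.loc[list(uniq), gf_id].to_numpy(dtype=float)
        sd = gcol.std()
        if sd == 0:
            raise ValueError(f"GF {gf_id!r} is constant among scanned patients")
        g = (gcol - gcol.mean()) / sd
        beta0, beta1, se1, sigma_u, sigma_e, theta, df = _profile_reml(
            g, counts, ybar, ssw, y.shape[0])
        p = _wald_p(beta1, se1, df, uniq.size)
        cat = gfs.categories[gf_id]
        for j, fid in enumerate(drfs.feature_ids):
            rows.append((fid, kernel_of.get(fid, 0), gf_id, cat,
                         beta1[j], p[j]))
    table = pd.DataFrame(rows, columns=["drf_id", "kernel", "gf_id",
                                        "gf_category", "beta1", "p"])

    table["p_adj"] = np.nan
    if bh_family == "global":
        groups = [np.arange(len(table))]
    else:
        groups = [np.flatnonzero((table["gf_category"] == c).to_numpy())
                  for c in CATEGORIES]
    for idx in groups:
        if idx.size:
            table.loc[table.index[idx], "p_adj"] = multipletests(
                table["p"].to_numpy()[idx], method="fdr_bh")[1]
    table["p_adj"] = np.maximum(table["p_adj"], table["p"])
    table["significant"] = table["p_adj"] < alpha
    return table


def count_per_kernel(table: pd.DataFrame,
                     n_kernels: int = N_KERNELS) -> pd.DataFrame:
    """Significant-association counts per kernel x GF category, with totals."""
    out = pd.DataFrame(0, index=pd.RangeIndex(1, n_kernels + 1, name="kernel"),
                       columns=list(CATEGORIES))
    sig = table[table["significant"]] if len(table) else table
    if len(sig):
        counts = sig.groupby(["kernel", "gf_category"]).size()
        for (k, c), v in counts.items():
            if k in out.index:
                out.loc[k, c] = v
    out["total"] = out.sum(axis=1)
    return out


def _feature_sort_key(fid: str) -> tuple:
    if "_" in fid and fid.rsplit("_", 1)[1].isdigit():
        return (fid.rsplit("_", 1)[0], int(fid.rsplit("_", 1)[1]))
    return (fid, 0)


def top_features(table: pd.DataFrame, k: int = 30) -> pd.DataFrame:
    """Top-k DRFs by number of significant GF associations, with category split."""
    if k < 1:
        raise ValueError("k must be >= 1")
    sig = table[table["significant"]]
    if not len(sig):
        return pd.DataFrame(columns=["drf_id", *CATEGORIES, "total", "kernel"])
    pivot = (sig.pivot_table(index="drf_id", columns="gf_category",
                             aggfunc="size", fill_value=0)
             .reindex(columns=list(CATEGORIES), fill_value=0))
    pivot["total"] = pivot.sum(axis=1)
    kernel = sig.groupby("drf_id")["kernel"].first()
    pivot["kernel"] = kernel
    pivot = pivot.reset_index()
    pivot = pivot.sort_values(
        by=["total", "drf_id"], ascending=[False, True],
        key=lambda s: s.map(_feature_sort_key) if s.name == "drf_id" else s)
    return pivot.head(k).reset_index(drop=True)


def top_gfs(table: pd.DataFrame, k_per_category: int = 5,
            n_top_kernels: int = 5) -> dict[str, pd.DataFrame]:
    """Per-category GFs ranked by significant-DRF count, with top kernels.

    For each reported GF, the kernels contributing the most significant
    DRFs are listed in descending count order (ties by kernel id).
    """
    if k_per_category < 1:
        raise ValueError("k_per_category must be >= 1")
    sig = table[table["significant"]]
    result: dict[str, pd.DataFrame] = {}
    for cat in CATEGORIES:
        sub = sig[sig["gf_category"] == cat]
        if not len(sub):
            result[cat] = pd.DataFrame(
                columns=["gf_id", "n_significant_drfs", "top_kernels"])
            continue
        counts = sub.groupby("gf_id").size().sort_values(ascending=False)
        counts = counts.sort_index().sort_values(ascending=False, kind="stable")
        rows = []
        for gf_id in counts.index[:k_per_category]:
            kc = sub[sub["gf_id"] == gf_id].groupby("kernel").size()
            kc = kc.sort_index().sort_values(ascending=False, kind="stable")
            rows.append((gf_id, int(counts[gf_id]),
                         list(kc.index[:n_top_kernels])))
        result[cat] = pd.DataFrame(
            rows, columns=["gf_id", "n_significant_drfs", "top_kernels"])
    return result
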