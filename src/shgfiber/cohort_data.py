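"""Reference summary statistics of a two-group TNBC SHG imaging cohort.

A published triple-negative breast cancer cohort (10 African American "AA"
and 17 Caucasian "C" tumor samples, 20 imaged sites per sample) underlies
the default study design of this package.  Its per-sample summary moments
(group mean and SD of each morphometric and FB-distribution feature) and the
variable-to-principal-component correlation structure are bundled here so
summary-statistic analyses (Welch t from printed moments, derived-metric
arithmetic, PCA structure checks) can run without the original images, which
are not publicly deposited.

Units follow the source report: area px^2, lengths px, HDM as a fraction,
curvature degrees, fiber thickness um, FB features in 8-bit ratio units.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

N_AA = 10
N_C = 17

#: morphometric per-sample summary: metric -> (AA mean, AA sd, C mean, C sd)
MORPHOMETRY_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "area": (5872.4, 802.57, 4439.3, 1002.94),
    "lacunarity": (45.4, 6.93, 68.1, 20.07),
    "total_length": (4724.3, 708.78, 3573.2, 772.60),
    "endpoints": (120.9, 23.78, 92.4, 14.42),
    "hgu": (41.7, 5.76, 41.6, 7.31),
    "branchpoints": (9.2, 3.52, 5.3, 1.51),
    "bcfd": (1.2, 0.03, 1.1, 0.05),
    "curvature": (29.3, 6.62, 25.4, 4.61),
    "hdm": (0.1, 0.03, 0.1, 0.05),
    "alignment": (0.4, 0.07, 0.4, 0.08),
    "avg_fiber_length": (73.8, 10.27, 73.4, 12.10),
    "fiber_thickness": (33.5, 9.88, 22.8, 13.59),
}

#: FB distribution features: feature -> (AA mean, AA sd, C mean, C sd)
FB_SUMMARY: dict[str, tuple[float, float, float, float]] = {
    "fb_mean": (20.9, 2.0, 26.6, 13.01),
    "fb_stddev": (28.4, 2.3, 41.1, 18.27),
    "fb_median": (13.6, 1.6, 13.4, 2.02),
    "fb_iqr": (15.2, 1.0, 17.6, 7.04),
    "n_measured": (218178.2, 119873.6, 70162.6, 47503.0),
    "n_zeros": (251356.9, 110885.2, 117668.2, 111813.0),
    "n_255": (144.9, 115.0, 42.0, 35.24),
    "total_n": (469680.0, 220448.2, 187872.8, 153960.0),
}

#: correlation of each standardized metric with the first three principal
#: components of the per-sample metrics table
PC_CORRELATIONS = pd.DataFrame(
    {
        "PC1": [0.975, -0.935, 0.975, 0.801, 0.303, 0.810, 0.969, 0.418, 0.660, -0.156, 0.298, 0.625],
        "PC2": [-0.069, 0.186, -0.061, 0.492, -0.894, 0.301, -0.116, 0.641, -0.182, -0.859, -0.883, 0.045],
        "PC3": [0.185, -0.099, 0.183, 0.144, 0.142, 0.246, 0.145, -0.012, -0.725, 0.002, 0.052, -0.772],
    },
    index=list(MORPHOMETRY_SUMMARY),
)


def metric_correlation_matrix() -> pd.DataFrame:
    """Approximate metric correlation matrix implied by the PC structure.

    The three variable-PC correlation vectors imply leading eigenvalues
    lambda_k = sum of squared correlations and eigenvectors proportional to
    the correlation columns.  The matrix is rebuilt with exactly that
    leading eigenstructure, a flat residual spectrum on the orthogonal
    complement (so the trace equals the number of variables), and a final
    rescale to unit diagonal.  Positive definite by construction.
    """
    L = PC_CORRELATIONS.to_numpy()
    p = L.shape[0]
    lam = (L**2).sum(axis=0)
    U, _ = np.linalg.qr(L / np.linalg.norm(L, axis=0))
    lam_resid = (p - lam.sum()) / (p - L.shape[1])
    R = U @ np.diag(lam) @ U.T + lam_resid * (np.eye(p) - U @ U.T)
    d = np.sqrt(np.diag(R))
    R = R / np.outer(d, d)
    return pd.DataFrame(R, index=PC_CORRELATIONS.index, columns=PC_CORRELATIONS.index)


def synthetic_sample_table(
    seed: int, group_shift: bool = True, exact_correlation: bool = False
) -> pd.DataFrame:
    """Synthetic stand-in for the cohort's per-sample metrics table.

    The real per-sample table is not deposited; this generates a labelled
    synthetic surrogate with the bundled group means/SDs and the
    PC-implied correlation structure.  With ``exact_correlation`` the
    sample correlation matrix of the (unshifted) data is made exactly equal
    to the reconstructed R (by whitening and re-coloring), so population
    and sample eigenstructure coincide; otherwise rows are ordinary
    multivariate normal draws.  ``group_shift`` applies the per-group means
    and SDs; without it all 27 rows share the pooled moments.
    """
    rng = np.random.default_rng(seed)
    metrics = list(MORPHOMETRY_SUMMARY)
    R = metric_correlation_matrix().to_numpy()
    n = N_AA + N_C
    p = len(metrics)
    z = rng.standard_normal((n, p))
    if exact_correlation:
        z = z - z.mean(axis=0)
        cov = np.cov(z, rowvar=False)
        z = z @ np.linalg.inv(np.linalg.cholesky(cov).T)
    z = z @ np.linalg.cholesky(R).T
    groups = ["AA"] * N_AA + ["C"] * N_C
    data = {}
    for j, m in enumerate(metrics):
        aa_mean, aa_sd, c_mean, c_sd = MORPHOMETRY_SUMMARY[m]
        if group_shift:
            mean = np.where([g == "AA" for g in groups], aa_mean, c_mean)
            sd = np.where([g == "AA" for g in groups], aa_sd, c_sd)
        else:
            mean = np.full(n, (N_AA * aa_mean + N_C * c_mean) / n)
            sd = np.full(n, (N_AA * aa_sd + N_C * c_sd) / n)
        data[m] = mean + sd * z[:, j]
    table = pd.DataFrame(data)
    table.insert(0, "group", groups)
    table.insert(0, "sample_id", [f"{g}{i:02d}" for i, g in enumerate(groups, 1)])
    return table
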