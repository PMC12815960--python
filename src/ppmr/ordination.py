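"""Family-level community matrix, non-metric multidimensional scaling, and
environmental vector fitting.

Prey are aggregated into families per ICES rectangle (abundance sums);
Bray-Curtis dissimilarities among family profiles are embedded by nMDS
(SMACOF with multiple random starts), and per-family covariates — mean
body mass, mean temperature, mean fishing effort — are fitted as vectors
onto the two ordination axes with an R-squared and a permutation p-value.

Configurations are centred and rotated to principal axes, with a fixed sign
convention, so results are reproducible and row-order invariant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.manifold import MDS

logger = logging.getLogger(__name__)

__all__ = [
    "CommunityMatrix",
    "OrdinationResult",
    "build_community_matrix",
    "run_nmds",
    "fit_env_vectors",
]


@dataclass
class CommunityMatrix:
    """Prey families x sites (ICES rectangles) abundance matrix with
    per-family covariates."""

    counts: pd.DataFrame  # index: family, columns: rectangle, cells: abundance
    covariates: pd.DataFrame  # index: family; mean mass/temperature/effort, modal size class


@dataclass
class OrdinationResult:
    coords: pd.DataFrame  # index: family, columns: axis1, axis2 (k axes)
    stress: float  # Kruskal stress-1
    vectors: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_community_matrix(
    matched_prey_df: pd.DataFrame, min_total_abundance: int = 5
) -> CommunityMatrix:
    """Sum prey abundance per family x rectangle; families whose total
    abundance falls below ``min_total_abundance`` are dropped and logged.
    Family covariates are abundance-weighted means."""
    if "prey_family" not in matched_prey_df.columns:
        raise ValueError("input has no prey_family column")
    df = matched_prey_df.copy()
    counts = (
        df.pivot_table(
            index="prey_family",
            columns="ices_rectangle",
            values="prey_count",
            aggfunc="sum",
            fill_value=0,
        )
        .astype(float)
    )
    totals = counts.sum(axis=1)
    keep = totals >= min_total_abundance
    if (~keep).any():
        logger.warning(
            "dropping %d famil(ies) below total abundance %d: %s",
            int((~keep).sum()),
            min_total_abundance,
            ", ".join(totals.index[~keep]),
        )
    counts = counts.loc[keep]
    if counts.empty:
        raise ValueError("no families left after abundance filtering")

    w = df["prey_count"].astype(float)
    cov_rows = {}
    from ppmr.size_structure import assign_size_classes

    df["_size_class"] = assign_size_classes(df["prey_indiv_mass_g"])
    for fam, grp in df.groupby("prey_family"):
        if fam not in counts.index:
            continue
        gw = w.loc[grp.index]
        wsum = gw.sum()
        row = {
            "mean_mass_g": float((gw * grp["prey_indiv_mass_g"]).sum() / wsum),
        }
        if "sst_c" in grp.columns:
            row["mean_temperature"] = float((gw * grp["sst_c"]).sum() / wsum)
        if "effort_hours" in grp.columns and grp["effort_hours"].notna().any():
            sel = grp["effort_hours"].notna()
            row["mean_effort_hours"] = float(
                (gw[sel] * grp.loc[sel, "effort_hours"]).sum() / gw[sel].sum()
            )
        counts_by_class = grp.groupby("_size_class")["prey_count"].sum()
        row["modal_size_class"] = counts_by_class.idxmax()
        cov_rows[fam] = row
    covariates = pd.DataFrame.from_dict(cov_rows, orient="index").loc[counts.index]
    return CommunityMatrix(counts=counts, covariates=covariates)


def _principal_axis_rotation(coords: np.ndarray) -> np.ndarray:
    coords = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(coords, full_matrices=False)
    rotated = coords @ vt.T
    # sign convention: the largest-magnitude coordinate on each axis is positive
    for j in range(rotated.shape[1]):
        i = int(np.argmax(np.abs(rotated[:, j])))
        if rotated[i, j] < 0:
            rotated[:, j] = -rotated[:, j]
    return rotated


def run_nmds(
    matrix: CommunityMatrix | pd.DataFrame,
    k: int = 2,
    seed: int = 0,
    n_starts: int = 20,
    max_iter: int = 500,
    tol: float = 1e-7,
    fourth_root: bool = False,
) -> OrdinationResult:
    """Non-metric MDS of Bray-Curtis dissimilarities among family rows.

    Runs SMACOF from ``n_starts`` random initialisations and keeps the best
    solution; reports Kruskal stress-1.  Coordinates are centred, rotated to
    principal axes and sign-fixed.  ``fourth_root`` optionally transforms
    abundances before the dissimilarity (default off).
    """
    counts = matrix.counts if isinstance(matrix, CommunityMatrix) else matrix
    if len(counts) < k + 1:
        raise ValueError(f"need at least {k + 1} rows for a {k}-D ordination")
    x = counts.to_numpy(dtype=float)
    if fourth_root:
        x = x**0.25
    dvec = pdist(x, metric="braycurtis")
    if not np.isfinite(dvec).all():
        raise ValueError("undefined Bray-Curtis dissimilarity (all-zero row?)")
    if np.allclose(dvec, 0.0):
        raise ValueError("degenerate dissimilarity matrix: all distances zero")
    dmat = squareform(dvec)
    mds = MDS(
        n_components=k,
        metric_mds=False,
        metric="precomputed",
        init="random",
        n_init=n_starts,
        max_iter=max_iter,
        eps=tol,
        random_state=seed,
        normalized_stress=True,
        n_jobs=1,
    )
    emb = mds.fit_transform(dmat)
    coords = _principal_axis_rotation(emb)
    cols = [f"axis{i + 1}" for i in range(k)]
    return OrdinationResult(
        coords=pd.DataFrame(coords, index=counts.index, columns=cols),
        stress=float(mds.stress_),
    )


def fit_env_vectors(
    coords: pd.DataFrame,
    covariates: pd.DataFrame,
    n_permutations: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Least-squares fit of each (numeric) covariate onto the ordination
    axes: arrow direction = normalised regression coefficients, R-squared of
    the regression, and a permutation p-value over row shuffles.

    A constant covariate yields R-squared 0 and is flagged."""
    rng = np.random.default_rng(seed)
    axes = coords.to_numpy(dtype=float)[:, :2]
    X = np.column_stack([np.ones(len(axes)), axes])
    rows = []
    for name in covariates.columns:
        v = covariates[name]
        if not pd.api.types.is_numeric_dtype(v):
            continue
        y = v.to_numpy(dtype=float)
        if np.isnan(y).any():
            mask = ~np.isnan(y)
        else:
            mask = np.ones(len(y), dtype=bool)
        yy, XX = y[mask], X[mask]
        note = ""
        if np.std(yy) < 1e-15:
            rows.append(
                {"covariate": name, "dx": 0.0, "dy": 0.0, "r2": 0.0, "p_perm": 1.0, "note": "constant covariate"}
            )
            continue

        def _r2_and_beta(yv):
            beta, *_ = np.linalg.lstsq(XX, yv, rcond=None)
            resid = yv - XX @ beta
            ss_res = float(resid @ resid)
            ss_tot = float(((yv - yv.mean()) ** 2).sum())
            return 1.0 - ss_res / ss_tot, beta

        r2, beta = _r2_and_beta(yy)
        norm = float(np.hypot(beta[1], beta[2]))
        dx, dy = (beta[1] / norm, beta[2] / norm) if norm > 0 else (0.0, 0.0)
        exceed = 0
        for _ in range(n_permutations):
            r2_p, _ = _r2_and_beta(rng.permutation(yy))
            if r2_p >= r2:
                exceed += 1
        p_perm = (1 + exceed) / (1 + n_permutations)
        rows.append(
            {"covariate": name, "dx": dx, "dy": dy, "r2": r2, "p_perm": p_perm, "note": note}
        )
    return pd.DataFrame(rows)
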