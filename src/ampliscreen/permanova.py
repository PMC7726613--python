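"""Sequential (Type I) distance-based PERMANOVA — the "adonis" variance partition.

Given an n x n dissimilarity matrix D and an ordered list of categorical
factors, the total sum of squares SS_total = tr(G), with G the Gower
double-centered matrix of D (equivalently (1/n) * sum_{i<j} d_ij^2).  Terms
are added in the stated order; the k-th term's sequential sum of squares is

    SS_k = tr((H_k - H_{k-1}) G)

where H_k is the hat (projection) matrix of the design containing the
intercept and the first k factors as treatment contrasts.  R^2_k =
SS_k / SS_total, pseudo-F_k = (SS_k / df_k) / (SS_res / df_res), and the
permutation p-value permutes the rows/columns of D jointly, counting
permuted statistics at least as large as the observed one with the +1
convention (identity permutation included), so the smallest attainable p is
1/(n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .community import gower_center

RANK_TOL = 1e-8
N_PERM_DEFAULT = 999


@dataclass
class FactorResult:
    name: str
    df: int
    ss: float
    r2: float
    pseudo_f: float  # nan when df == 0
    p_value: float  # nan when df == 0


@dataclass
class PermanovaResult:
    factors: list[FactorResult]
    residual_df: int
    residual_ss: float
    total_ss: float
    n_permutations: int
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "factor": f.name,
                "df": f.df,
                "SS": f.ss,
                "R2": f.r2,
                "pseudo_F": f.pseudo_f,
                "p_value": f.p_value,
            }
            for f in self.factors
        ]
        rows.append(
            {
                "factor": "Residuals",
                "df": self.residual_df,
                "SS": self.residual_ss,
                "R2": self.residual_ss / self.total_ss if self.total_ss else np.nan,
                "pseudo_F": np.nan,
                "p_value": np.nan,
            }
        )
        return pd.DataFrame(rows)


def _dummy_columns(values: np.ndarray) -> np.ndarray:
    """Treatment-contrast columns (first level dropped) for one factor."""
    levels = pd.unique(values)
    return np.column_stack([(values == lv).astype(float) for lv in levels[1:]]) if len(levels) > 1 \
        else np.empty((len(values), 0))


def _hat(X: np.ndarray, tol: float = RANK_TOL) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto col(X) and its rank, via SVD."""
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    rank = int((s > tol * (s[0] if s.size else 1.0)).sum())
    Ur = U[:, :rank]
    return Ur @ Ur.T, rank


def permanova(
    dm: DistanceMatrix | np.ndarray,
    metadata: pd.DataFrame,
    factor_order: list[str],
    n_perm: int = N_PERM_DEFAULT,
    seed: int | None = 0,
) -> PermanovaResult:
    """Sequential PERMANOVA of ``dm`` on the ordered categorical factors.

    ``metadata`` must define every factor for every sample in the matrix
    (rows are aligned by sample id when ``dm`` is a labelled matrix).  A
    constant or fully collinear factor receives df 0, SS 0 and an undefined
    (NaN) p-value, mirroring a dropped term.
    """
    if isinstance(dm, DistanceMatrix):
        d = dm.data
        ids = list(dm.ids)
        missing = set(ids) - set(metadata.index)
        if missing:
            raise ValueError(f"factors undefined for samples: {sorted(missing)}")
        meta = metadata.loc[ids]
    else:
        d = np.asarray(dm, dtype=float)
        if len(metadata) != d.shape[0]:
            raise ValueError("metadata length does not match distance matrix")
        meta = metadata
    for f in factor_order:
        if f not in meta.columns:
            raise ValueError(f"unknown factor {f!r}")
        if meta[f].isna().any():
            raise ValueError(f"factor {f!r} undefined for some samples")

    n = d.shape[0]
    G = gower_center(d)
    ss_total = float(np.trace(G))

    # Nested designs: intercept, then cumulative factor blocks.
    X = np.ones((n, 1))
    hats = []
    ranks = []
    H_prev, r_prev = _hat(X)
    for f in factor_order:
        X = np.column_stack([X, _dummy_columns(meta[f].to_numpy())])
        H, r = _hat(X)
        hats.append(H - H_prev)
        ranks.append(r - r_prev)
        H_prev, r_prev = H, r
    H_full, rank_full = H_prev, r_prev
    R = np.eye(n) - H_full
    df_res = n - rank_full
    # residual SS can be a tiny negative number in exact-fit designs
    ss_res = max(float(np.sum(R * G)), 0.0)

    ss_terms = np.array([float(np.sum(M * G)) for M in hats])
    dfs = np.array(ranks)

    with np.errstate(divide="ignore", invalid="ignore"):
        f_obs = (ss_terms / np.where(dfs == 0, np.nan, dfs)) / (ss_res / df_res)

    # Permutation test: permute rows/columns of D (hence G) jointly.  Ties in
    # the permuted statistic count as "at least as extreme" (tolerance guards
    # against float jitter between algebraically equal statistics).
    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(factor_order))
    valid = dfs > 0
    thresholds = np.where(
        np.isfinite(f_obs), f_obs - 1e-10 * np.maximum(1.0, np.abs(f_obs)), f_obs
    )
    for _ in range(n_perm):
        p = rng.permutation(n)
        Gp = G[np.ix_(p, p)]
        ss_res_p = max(float(np.sum(R * Gp)), 0.0)
        for k, M in enumerate(hats):
            if not valid[k]:
                continue
            with np.errstate(divide="ignore", invalid="ignore"):
                f_p = (np.sum(M * Gp) / dfs[k]) / (ss_res_p / df_res)
            if f_p >= thresholds[k]:
                exceed[k] += 1
    p_values = (1.0 + exceed) / (1.0 + n_perm)

    factors = []
    for k, name in enumerate(factor_order):
        factors.append(
            FactorResult(
                name=name,
                df=int(dfs[k]),
                ss=float(ss_terms[k]),
                r2=float(ss_terms[k] / ss_total) if ss_total else np.nan,
                pseudo_f=float(f_obs[k]) if valid[k] else float("nan"),
                p_value=float(p_values[k]) if valid[k] else float("nan"),
            )
        )
    return PermanovaResult(
        factors=factors,
        residual_df=int(df_res),
        residual_ss=ss_res,
        total_ss=ss_total,
        n_permutations=n_perm,
        seed=seed,
    )
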