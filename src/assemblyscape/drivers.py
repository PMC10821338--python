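"""Driver attribution for βNTI variation: geographic and environmental
distance matrices, standard and partial Mantel tests.

The Mantel correlation is the plain (Pearson or Spearman) correlation of the
vectorised upper triangles; significance comes from jointly permuting the
rows and columns of the first matrix.  The partial Mantel statistic is the
first-order partial correlation r_xy·z; its permutation scheme permutes x and
recomputes the partial statistic each time.  One-tailed (positive
association) by default, the ecological convention for distance matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pairwise import PairwiseMatrix, align

EARTH_RADIUS_KM = 6371.0

ENV_VARIABLES = ("temperature", "salinity", "latitude")


def haversine_km(lat1, lon1, lat2, lon2) -> float:
    """Great-circle distance between two points, mean Earth radius 6371 km."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dphi = phi2 - phi1
    dlam = np.radians(lon2) - np.radians(lon1)
    a = np.sin(dphi / 2.0) ** 2 + np.cos(phi1) * np.cos(phi2) * np.sin(dlam / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a)))


def haversine_matrix(metadata: pd.DataFrame) -> PairwiseMatrix:
    """Pairwise great-circle distances (km) between sample coordinates."""
    for col in ("latitude", "longitude"):
        if col not in metadata.columns:
            raise ValueError(f"metadata missing column {col!r}")
        if metadata[col].isna().any():
            bad = metadata.index[metadata[col].isna()].tolist()
            raise ValueError(f"missing {col} for samples: {bad}")
    lat = np.radians(metadata["latitude"].to_numpy(dtype=float))
    lon = np.radians(metadata["longitude"].to_numpy(dtype=float))
    dphi = lat[:, None] - lat[None, :]
    dlam = lon[:, None] - lon[None, :]
    a = np.sin(dphi / 2.0) ** 2 + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlam / 2.0) ** 2
    a = np.clip(a, 0.0, 1.0)
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))
    np.fill_diagonal(d, 0.0)
    d = 0.5 * (d + d.T)
    return PairwiseMatrix([str(s) for s in metadata.index], d, kind="geographic_km")


def env_delta_matrix(metadata: pd.DataFrame, variable: str) -> PairwiseMatrix:
    """Pairwise absolute differences |v_i − v_j| of an environmental variable."""
    if variable not in ENV_VARIABLES:
        raise ValueError(f"variable must be one of {ENV_VARIABLES}")
    if variable not in metadata.columns:
        raise ValueError(f"metadata missing column {variable!r}")
    v = metadata[variable]
    if v.isna().any():
        raise ValueError(f"missing {variable} for samples: {v.index[v.isna()].tolist()}")
    x = v.to_numpy(dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    kind = "delta_latitude" if variable == "latitude" else "delta_env"
    return PairwiseMatrix([str(s) for s in metadata.index], d, kind=kind)


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    tail: str = "greater"
    controlled: list[str] = field(default_factory=list)


def _rank_square(m: np.ndarray) -> np.ndarray:
    """Replace upper-triangle values by their ranks, mirrored symmetrically.

    Permuting rows/columns of a matrix only rearranges its condensed entries,
    so Spearman under permutation equals Pearson on this pre-ranked matrix.
    """
    n = m.shape[0]
    iu = np.triu_indices(n, k=1)
    out = np.zeros_like(m, dtype=float)
    r = stats.rankdata(m[iu])
    out[iu] = r
    out.T[iu] = r
    return out


def _condensed(m: np.ndarray) -> np.ndarray:
    return m[np.triu_indices(m.shape[0], k=1)]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("constant matrix: correlation undefined")
    return float((xc @ yc) / denom)


def _p_from_null(r_obs: float, r_null: np.ndarray, tail: str) -> float:
    if tail == "greater":
        count = (r_null >= r_obs).sum()
    elif tail == "two-sided":
        count = (np.abs(r_null) >= abs(r_obs)).sum()
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float((1 + count) / (1 + r_null.size))


def mantel(
    x: PairwiseMatrix,
    y: PairwiseMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Standard Mantel test between two pairwise matrices.

    r is the correlation of the vectorised upper triangles; the permutation
    null jointly permutes rows/columns of ``x``.  p uses the add-one
    estimator, one-tailed toward positive association by default
    (``tail="two-sided"`` available).
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    xm, ym = align(x, y)
    xv = xm.values
    if method == "spearman":
        xv = _rank_square(xv)
        yv = _rank_square(ym.values)
    else:
        yv = ym.values
    yc = _condensed(yv)
    r_obs = _pearson(_condensed(xv), yc)
    rng = np.random.default_rng(seed)
    n = xm.n_samples
    r_null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        r_null[i] = _pearson(_condensed(xv[np.ix_(perm, perm)]), yc)
    return MantelResult(r_obs, _p_from_null(r_obs, r_null, tail), n_perm, method, tail)


def _partial_r(xv, yv, zv) -> float:
    rxy = _pearson(xv, yv)
    rxz = _pearson(xv, zv)
    ryz = _pearson(yv, zv)
    denom = np.sqrt((1 - rxz**2) * (1 - ryz**2))
    if denom == 0:
        raise ValueError("degenerate control: |r_xz| or |r_yz| equals 1")
    return (rxy - rxz * ryz) / denom


def partial_mantel(
    x: PairwiseMatrix,
    y: PairwiseMatrix,
    z: PairwiseMatrix,
    method: str = "spearman",
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
    controlled_name: str = "z",
) -> MantelResult:
    """Partial Mantel test of x vs y controlling z.

    r_xy·z = (r_xy − r_xz·r_yz) / √((1−r_xz²)(1−r_yz²)) over upper triangles;
    the permutation null permutes x and recomputes the partial statistic.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError("method must be 'pearson' or 'spearman'")
    xm, ym, zm = align(x, y, z)
    if method == "spearman":
        xv, yv, zv = (_rank_square(m.values) for m in (xm, ym, zm))
    else:
        xv, yv, zv = xm.values, ym.values, zm.values
    yc, zc = _condensed(yv), _condensed(zv)
    r_obs = _partial_r(_condensed(xv), yc, zc)
    rng = np.random.default_rng(seed)
    n = xm.n_samples
    r_null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n)
        r_null[i] = _partial_r(_condensed(xv[np.ix_(perm, perm)]), yc, zc)
    res = MantelResult(float(r_obs), _p_from_null(r_obs, r_null, tail), n_perm, method, tail)
    res.controlled = [controlled_name]
    return res


def _sequential_partial(xv, yv, controls: list[np.ndarray]) -> np.ndarray:
    """Residualise the condensed vectors on each control in turn (OLS)."""
    def residual(v, c):
        c1 = np.column_stack([np.ones_like(c), c])
        beta, *_ = np.linalg.lstsq(c1, v, rcond=None)
        return v - c1 @ beta

    for c in controls:
        xv = residual(xv, c)
        yv = residual(yv, c)
    return xv, yv


def driver_analysis(
    bnti: PairwiseMatrix,
    drivers: dict[str, PairwiseMatrix],
    n_perm: int = 999,
    seed: int = 0,
    method: str = "spearman",
) -> pd.DataFrame:
    """Standard and partial Mantel tests of βNTI against candidate drivers.

    For each driver matrix (e.g. Δtemperature, Δsalinity, geographic
    distance, Δlatitude) this reports the standard Mantel test, first-order
    partial Mantel tests controlling each other driver in turn, and a partial
    test controlling all other drivers at once (sequential residualisation).
    Rows are ranked by the all-others partial r.
    """
    if len(drivers) < 2:
        raise ValueError("need at least 2 driver matrices")
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(drivers) * (len(drivers) + 1), dtype=np.uint32) % (2**31))
    rows = []
    names = list(drivers)
    for name in names:
        std = mantel(bnti, drivers[name], method=method, n_perm=n_perm, seed=int(next(seeds)))
        rows.append(
            {"driver": name, "controlled": "", "r": std.r, "p": std.p,
             "n_perm": n_perm, "method": method}
        )
        for other in names:
            if other == name:
                continue
            try:
                pm = partial_mantel(
                    bnti, drivers[name], drivers[other], method=method,
                    n_perm=n_perm, seed=int(next(seeds)), controlled_name=other,
                )
                r_val, p_val = pm.r, pm.p
            except ValueError:
                # degenerate control (e.g. a driver duplicating the response)
                r_val, p_val = float("nan"), float("nan")
            rows.append(
                {"driver": name, "controlled": other, "r": r_val, "p": p_val,
                 "n_perm": n_perm, "method": method}
            )
        # all-others control via sequential residualisation + permutation of x
        others = [o for o in names if o != name]
        xm, ym, *zs = align(bnti, drivers[name], *[drivers[o] for o in others])
        if method == "spearman":
            xv_m = _rank_square(xm.values)
            yv = _condensed(_rank_square(ym.values))
            zc = [_condensed(_rank_square(z.values)) for z in zs]
        else:
            xv_m = xm.values
            yv = _condensed(ym.values)
            zc = [_condensed(z.values) for z in zs]
        xr, yr = _sequential_partial(_condensed(xv_m), yv, zc)
        r_obs = _pearson(xr, yr)
        rng = np.random.default_rng(int(next(seeds)))
        n = xm.n_samples
        r_null = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(n)
            xp, yp = _sequential_partial(_condensed(xv_m[np.ix_(perm, perm)]), yv, zc)
            r_null[i] = _pearson(xp, yp)
        rows.append(
            {"driver": name, "controlled": "+".join(others), "r": float(r_obs),
             "p": _p_from_null(r_obs, r_null, "greater"), "n_perm": n_perm,
             "method": method}
        )
    df = pd.DataFrame(rows)
    # rank drivers by their all-others partial r
    combined = df[df["controlled"].str.contains(r"\+", regex=True) | df["controlled"].eq(
        df["driver"].map(lambda d: "+".join([o for o in names if o != d]))
    )]
    order = (
        combined.sort_values("r", ascending=False)["driver"].drop_duplicates().tolist()
    )
    df["driver"] = pd.Categorical(df["driver"], categories=order, ordered=True)
    return df.sort_values(["driver", "controlled"]).reset_index(drop=True)
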