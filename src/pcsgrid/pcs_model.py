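"""Pseudocontact-shift physics: geometry rows, tensor fit, Q-factor.

A nucleus at distance r from a paramagnetic ion experiences a pseudocontact
shift (PCS, ppm) determined by the anisotropic part of the ion's magnetic
susceptibility tensor Δχ (a 3×3 symmetric traceless matrix, 5 independent
components, units m³):

    δ = (1 / 12π r⁵) · Σᵢⱼ Δχᵢⱼ (3 rᵢ rⱼ − r² δᵢⱼ)

Stacking one geometry row per measured nucleus gives the linear system
M·v = P which is solved by least squares for the 5-vector v. The geometry
row basis used here is

    (1/12π r⁵) · [½(2z²−x²−y²), ½(x²−y²), 2xy, 2xz, 2yz] · 10⁶

with (x, y, z) the ion→nucleus vector in meters, so that row·v is directly
in ppm. In this basis v = 3·(Tzz, Txx−Tyy, Txy, Txz, Tyz) for the traceless
tensor T ("physical" convention); a "literal" convention identifying the v
components with the tensor elements directly is also available, since
published principal values do not always state the reconstruction.

Goodness of fit is the Q-factor

    Q = Σ(PCS_obs − PCS_calc)² / Σ(PCS_obs)²

with no square root: 0 is perfect agreement, 1 is the score of an all-zero
back-calculation.
"""
from __future__ import annotations

import io
import json
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .structures import MethylSite, StructureModel

logger = logging.getLogger(__name__)

ANGSTROM = 1e-10  # m
PPM = 1e6
MIN_ION_DISTANCE = 0.1  # Å; closer means a malformed model
CONDITION_WARN = 1e6  # condition number of M above which a warning is logged

PCS_TABLE_COLUMNS = [
    "residue_number",
    "residue_type",
    "methyl_label",
    "nucleus",
    "domain",
    "condition",
    "pcs_ppm",
]

_CONVENTIONS = ("physical", "literal")


def _v_to_matrix(v: np.ndarray, convention: str) -> np.ndarray:
    """Reconstruct the traceless symmetric 3×3 tensor from the fitted 5-vector."""
    scale = 3.0 if convention == "physical" else 1.0
    tzz = v[0] / scale
    txx = (v[1] / scale - tzz) / 2.0
    tyy = -(tzz + v[1] / scale) / 2.0
    txy, txz, tyz = v[2] / scale, v[3] / scale, v[4] / scale
    return np.array([[txx, txy, txz], [txy, tyy, tyz], [txz, tyz, tzz]])


def _matrix_to_v(t: np.ndarray, convention: str) -> np.ndarray:
    scale = 3.0 if convention == "physical" else 1.0
    return scale * np.array(
        [t[2, 2], t[0, 0] - t[1, 1], t[0, 1], t[0, 2], t[1, 2]]
    )


@dataclass(frozen=True)
class ChiTensor:
    """Fitted magnetic susceptibility anisotropy tensor.

    Attributes
    ----------
    v : (5,) ndarray
        Fitted components in m³ (the solution of M·v = P).
    convention : str
        ``"physical"`` (default; v = 3·(Tzz, Txx−Tyy, Txy, Txz, Tyz)) or
        ``"literal"`` (v components taken as tensor elements).
    q : float or None
        Fit residual Q-factor, when produced by a fit.
    n : int or None
        Number of PCS rows used in the fit.
    """

    v: np.ndarray
    convention: str = "physical"
    q: float | None = None
    n: int | None = None

    def __post_init__(self):
        if self.convention not in _CONVENTIONS:
            raise ValueError(f"unknown tensor convention {self.convention!r}")
        v = np.asarray(self.v, dtype=float)
        if v.shape != (5,) or not np.all(np.isfinite(v)):
            raise ValueError("v must be a finite 5-vector")
        object.__setattr__(self, "v", v)

    @classmethod
    def from_matrix(cls, t: np.ndarray, convention: str = "physical", **kw) -> "ChiTensor":
        t = np.asarray(t, dtype=float)
        if not np.allclose(t, t.T, atol=1e-14 * max(1.0, np.abs(t).max())):
            raise ValueError("tensor matrix must be symmetric")
        if abs(np.trace(t)) > 1e-10 * max(np.abs(t).max(), 1e-300):
            raise ValueError("tensor matrix must be traceless")
        return cls(v=_matrix_to_v(t, convention), convention=convention, **kw)

    @property
    def matrix(self) -> np.ndarray:
        """The 3×3 symmetric traceless tensor in m³."""
        return _v_to_matrix(self.v, self.convention)

    @property
    def principal_values(self) -> np.ndarray:
        """Eigenvalues sorted by |value| ascending: (Δχxx, Δχyy, Δχzz)."""
        w, _ = self._eig()
        return w

    @property
    def principal_axes(self) -> np.ndarray:
        """Orthonormal eigenvectors as columns, matching principal_values order."""
        _, vec = self._eig()
        return vec

    def _eig(self) -> tuple[np.ndarray, np.ndarray]:
        w, vec = np.linalg.eigh(self.matrix)
        order = np.argsort(np.abs(w))
        return w[order], vec[:, order]

    def to_json(self) -> str:
        w, vec = self._eig()
        return json.dumps(
            {
                "v": self.v.tolist(),
                "convention": self.convention,
                "matrix": self.matrix.tolist(),
                "principal_values": w.tolist(),
                "principal_axes": vec.tolist(),
                "q": self.q,
                "n": self.n,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ChiTensor":
        d = json.loads(text)
        return cls(
            v=np.array(d["v"]), convention=d["convention"], q=d.get("q"), n=d.get("n")
        )


# ---------------------------------------------------------------------------
# Geometry rows and forward calculation
# ---------------------------------------------------------------------------

def geometry_row(ion_position: np.ndarray, nucleus_position: np.ndarray) -> np.ndarray:
    """Single geometry row (ppm per m³) for one nucleus. Positions in Å."""
    return geometry_matrix(ion_position, np.asarray(nucleus_position, float)[None, :])[0]


def geometry_matrix(
    ion_position: np.ndarray, positions: np.ndarray, clamp: bool = False
) -> np.ndarray:
    """Stacked geometry rows for an (..., 3) array of nucleus positions (Å).

    Row basis: (10⁶/12π r⁵)·[½(2z²−x²−y²), ½(x²−y²), 2xy, 2xz, 2yz] with
    the ion→nucleus vector in meters. A nucleus closer than 0.1 Å to the
    ion signals a malformed model; with ``clamp=True`` the distance is
    floored instead (the resulting huge PCS makes such a geometry score
    arbitrarily badly, which is the desired behavior when scanning
    candidate conformers that may sweep through the ion).
    """
    ion = np.asarray(ion_position, dtype=float)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    d_ang = pos - ion
    r_ang = np.linalg.norm(d_ang, axis=-1)
    if np.any(r_ang < MIN_ION_DISTANCE):
        if not clamp:
            r_min = float(r_ang.min())
            raise ValueError(
                f"a nucleus is {r_min:.3g} Å from the ion: malformed model"
            )
        r_ang = np.maximum(r_ang, MIN_ION_DISTANCE)
    d = d_ang * ANGSTROM
    x, y, z = d[..., 0], d[..., 1], d[..., 2]
    r = r_ang * ANGSTROM
    pref = PPM / (12.0 * np.pi * r**5)
    rows = np.stack(
        [
            0.5 * (2 * z**2 - x**2 - y**2),
            0.5 * (x**2 - y**2),
            2 * x * y,
            2 * x * z,
            2 * y * z,
        ],
        axis=-1,
    )
    return pref[..., None] * rows


def forward_pcs(
    tensor: ChiTensor,
    ion_position: np.ndarray,
    sites: Sequence[MethylSite] | np.ndarray,
) -> np.ndarray:
    """Back-calculate PCSs (ppm) for sites; linear in the tensor."""
    if isinstance(sites, np.ndarray):
        return geometry_matrix(ion_position, sites) @ tensor.v
    sites = list(sites)
    if len(sites) == 0:
        raise ValueError("no sites given")
    positions = np.array([s.position for s in sites])
    r = np.linalg.norm(positions - np.asarray(ion_position, float), axis=1)
    if np.any(r < MIN_ION_DISTANCE):
        bad = sites[int(np.argmin(r))]
        raise ValueError(
            f"site {bad.key} is {r.min():.3g} Å from the ion: malformed model"
        )
    return geometry_matrix(ion_position, positions) @ tensor.v


# ---------------------------------------------------------------------------
# Measurement tables
# ---------------------------------------------------------------------------

def read_pcs_table(source) -> pd.DataFrame:
    """Read a tab-separated PCS table (path, file object, or text)."""
    if isinstance(source, str) and "\t" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, sep="\t")
    missing = [c for c in PCS_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PCS table missing columns: {missing}")
    validate_pcs_table(df)
    return df


def write_pcs_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def validate_pcs_table(df: pd.DataFrame) -> None:
    if not np.all(np.isfinite(df["pcs_ppm"].to_numpy(float))):
        raise ValueError("non-finite PCS values")
    key = ["residue_number", "methyl_label", "nucleus", "condition"]
    if df.duplicated(subset=key).any():
        raise ValueError("duplicate (residue, methyl, nucleus, condition) rows")


def _match_sites(
    measurements: pd.DataFrame, sites: Sequence[MethylSite]
) -> np.ndarray:
    """Positions (n, 3) for each measurement row, matched by (residue, label).

    Both ¹H and ¹³C rows of one methyl use the carbon coordinates: the
    structural model tabulates methyl carbons only.
    """
    site_map = {s.key: s for s in sites}
    positions = []
    for row in measurements.itertuples(index=False):
        key = (int(row.residue_number), str(row.methyl_label))
        site = site_map.get(key)
        if site is None:
            raise ValueError(f"measurement {key} has no matching methyl site")
        positions.append(site.position)
    return np.array(positions)


# ---------------------------------------------------------------------------
# Tensor fitting
# ---------------------------------------------------------------------------

def fit_tensor(
    measurements: pd.DataFrame,
    sites: Sequence[MethylSite],
    ion_position: np.ndarray,
    convention: str = "physical",
) -> ChiTensor:
    """Least-squares solve of M·v = P for the 5 tensor components.

    Requires at least 5 measurements and a full-rank geometry matrix
    (rank 5). Records the fit Q-factor and n on the returned tensor.
    """
    return fit_tensor_combined([(measurements, sites, ion_position)], convention)


def fit_tensor_combined(
    datasets: Iterable[tuple[pd.DataFrame, Sequence[MethylSite], np.ndarray]],
    convention: str = "physical",
) -> ChiTensor:
    """Fit one tensor to several pooled datasets (stacked rows).

    Pooling measurements from different conditions with identical geometry
    simply duplicates geometry rows with different observed values; the
    least-squares solution then fits their mean behavior.
    """
    blocks_m, blocks_p = [], []
    for measurements, sites, ion_position in datasets:
        if len(measurements) == 0:
            continue
        positions = _match_sites(measurements, sites)
        blocks_m.append(geometry_matrix(ion_position, positions))
        blocks_p.append(measurements["pcs_ppm"].to_numpy(float))
    if not blocks_m:
        raise ValueError("underdetermined: no measurements")
    m = np.vstack(blocks_m)
    p = np.concatenate(blocks_p)
    if len(p) < 5:
        raise ValueError(f"underdetermined: {len(p)} PCS values, need at least 5")
    rank = np.linalg.matrix_rank(m)
    if rank < 5:
        raise ValueError(
            f"degenerate geometry: geometry matrix has rank {rank} < 5"
        )
    cond = np.linalg.cond(m)
    if cond > CONDITION_WARN:
        logger.warning("geometry matrix condition number %.3g exceeds %g", cond, CONDITION_WARN)
    v, *_ = np.linalg.lstsq(m, p, rcond=None)
    calc = m @ v
    q = q_factor(p, calc)
    return ChiTensor(v=v, convention=convention, q=q, n=len(p))


def q_factor(observed: Sequence[float], calculated: Sequence[float]) -> float:
    """Q = Σ(obs−calc)² / Σ(obs)²; 0 iff obs == calc."""
    obs = np.asarray(observed, dtype=float)
    calc = np.asarray(calculated, dtype=float)
    if obs.shape != calc.shape or obs.size == 0:
        raise ValueError("observed and calculated must be equal-length, non-empty")
    denom = float(np.sum(obs**2))
    if denom == 0.0:
        raise ValueError("undefined Q: observed values are all zero")
    return float(np.sum((obs - calc) ** 2) / denom)


def pcs_change_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Mean absolute PCS change between bound and unbound per domain.

    Pairs rows on (residue_number, methyl_label, nucleus) present in both
    conditions and averages |PCS_bound − PCS_unbound| within each domain —
    the bound/unbound comparison stage of the analysis.
    """
    key = ["residue_number", "methyl_label", "nucleus", "domain"]
    bound = table[table["condition"] == "bound"].set_index(key)["pcs_ppm"]
    unbound = table[table["condition"] == "unbound"].set_index(key)["pcs_ppm"]
    common = bound.index.intersection(unbound.index)
    if len(common) == 0:
        raise ValueError("no (residue, methyl, nucleus) shared between conditions")
    delta = (bound.loc[common] - unbound.loc[common]).abs().reset_index()
    out = (
        delta.groupby("domain")["pcs_ppm"]
        .agg(mean_abs_change="mean", n="count")
        .reset_index()
    )
    return out
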