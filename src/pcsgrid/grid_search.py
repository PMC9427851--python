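"""Rigid-body orientation grid search for the mobile (Ig1) domain.

The tensor is fitted once from the tagged (Ig2) domain's PCS data and held
fixed; the mobile domain is rotated about the linker pivot through a ZXZ
Euler grid and every orientation is scored by the Q-factor between observed
and back-calculated PCSs. Default grid: alpha, gamma in [-90, 90] and beta
in [0, 180], 50 evenly spaced values per angle inclusive of endpoints
(50^3 = 125,000 orientations).

Scoring is vectorized over the whole grid: rotation matrices for all angle
triples are built in one batch and applied to the mobile-domain coordinates
with a single einsum, so a full 125,000-orientation search over a dozen
methyls takes seconds.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .pcs_model import ChiTensor, _match_sites, geometry_matrix, q_factor
from .structures import (
    EulerOrientation,
    StructureModel,
    rotate_domain,
    write_model_pdb,
)

DEFAULT_ALPHA_RANGE = (-90.0, 90.0)
DEFAULT_BETA_RANGE = (0.0, 180.0)
DEFAULT_GAMMA_RANGE = (-90.0, 90.0)
GIMBAL_TOL = 1e-9  # deg; beta this close to 0 flags an alpha/gamma-degenerate node


@dataclass(frozen=True)
class GridSpec:
    """Euler-angle grid: inclusive ranges and points per angle."""

    alpha_range: tuple[float, float] = DEFAULT_ALPHA_RANGE
    beta_range: tuple[float, float] = DEFAULT_BETA_RANGE
    gamma_range: tuple[float, float] = DEFAULT_GAMMA_RANGE
    n_per_angle: int = 50

    def __post_init__(self):
        if self.n_per_angle < 2:
            raise ValueError("n_per_angle must be >= 2")
        for name in ("alpha_range", "beta_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if not (np.isfinite(lo) and np.isfinite(hi)) or hi <= lo:
                raise ValueError(f"degenerate {name}: {(lo, hi)}")

    @property
    def size(self) -> int:
        return self.n_per_angle**3

    def axis_values(self, angle: str) -> np.ndarray:
        lo, hi = getattr(self, f"{angle}_range")
        return np.linspace(lo, hi, self.n_per_angle)


def make_grid(spec: GridSpec) -> np.ndarray:
    """(N, 3) array of (alpha, beta, gamma) triples, endpoints inclusive.

    Ordering is deterministic: alpha outermost, beta middle, gamma
    innermost (row-major Cartesian product).
    """
    a = spec.axis_values("alpha")
    b = spec.axis_values("beta")
    g = spec.axis_values("gamma")
    aa, bb, gg = np.meshgrid(a, b, g, indexing="ij")
    return np.column_stack([aa.ravel(), bb.ravel(), gg.ravel()])


@dataclass(frozen=True)
class GridResult:
    """Scored grid: angle triples, Q values, and the tensor used."""

    angles: np.ndarray  # (N, 3) degrees
    q: np.ndarray  # (N,)
    spec: GridSpec
    tensor: ChiTensor
    domain: str = "Ig1"
    top_n: int = 20
    provenance: dict = field(default_factory=dict)

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.q))  # argmin: ties resolve to grid order

    @property
    def best(self) -> tuple[EulerOrientation, float]:
        i = self.best_index
        return EulerOrientation(*self.angles[i]), float(self.q[i])

    def top(self, n: int | None = None) -> pd.DataFrame:
        """The n lowest-Q entries, ascending, ties broken by grid order."""
        n = self.top_n if n is None else n
        order = np.lexsort((np.arange(len(self.q)), self.q))[:n]
        df = pd.DataFrame(self.angles[order], columns=["alpha", "beta", "gamma"])
        df["Q"] = self.q[order]
        df["gimbal_degenerate"] = np.abs(df["beta"]) < GIMBAL_TOL
        df.index = order
        return df

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.angles, columns=["alpha", "beta", "gamma"])
        df["Q"] = self.q
        return df


def score_orientation(
    orientation: EulerOrientation,
    base_structure: StructureModel,
    tensor: ChiTensor,
    measurements: pd.DataFrame,
    domain: str = "Ig1",
) -> float:
    """Q-factor of one candidate orientation of the mobile domain.

    Rotates ``domain`` about the pivot, back-calculates PCSs with the fixed
    tensor, and compares with the observed values. Pure function.
    """
    _check_domain(measurements, domain)
    rotated = rotate_domain(base_structure, domain, orientation)
    positions = _match_sites(measurements, rotated.sites_in_domain(domain))
    calc = geometry_matrix(rotated.ion_position, positions) @ tensor.v
    return q_factor(measurements["pcs_ppm"].to_numpy(float), calc)


def _check_domain(measurements: pd.DataFrame, domain: str) -> None:
    other = set(measurements["domain"].unique()) - {domain}
    if other:
        raise ValueError(f"measurements include domains outside {domain!r}: {other}")


def run_grid_search(
    spec: GridSpec,
    base_structure: StructureModel,
    tensor: ChiTensor,
    measurements: pd.DataFrame,
    domain: str = "Ig1",
    top_n: int = 20,
    provenance: dict | None = None,
) -> GridResult:
    """Score every grid orientation of the mobile domain; fully vectorized.

    Results are independent of evaluation order; ties in Q resolve by grid
    ordering (alpha outer, beta middle, gamma inner).
    """
    _check_domain(measurements, domain)
    angles = make_grid(spec)
    sites = base_structure.sites_in_domain(domain)
    if not sites:
        raise ValueError(f"no sites in domain {domain!r}")
    positions = _match_sites(measurements, sites)  # (k, 3), one per measurement row
    obs = measurements["pcs_ppm"].to_numpy(float)
    pivot = base_structure.pivot_ca
    ion = base_structure.ion_position

    # intrinsic ZXZ matrices for all grid nodes at once
    rots = Rotation.from_euler("ZXZ", angles, degrees=True).as_matrix()  # (N,3,3)
    local = positions - pivot  # (k, 3)
    moved = np.einsum("nij,kj->nki", rots, local) + pivot  # (N, k, 3)
    # clashing conformers (site swept onto the ion) score huge Q, not an error
    rows = geometry_matrix(ion, moved, clamp=True)  # (N, k, 5)
    calc = rows @ tensor.v  # (N, k)
    denom = float(np.sum(obs**2))
    if denom == 0.0:
        raise ValueError("undefined Q: observed values are all zero")
    q = np.sum((calc - obs) ** 2, axis=1) / denom
    return GridResult(
        angles=angles,
        q=q,
        spec=spec,
        tensor=tensor,
        domain=domain,
        top_n=top_n,
        provenance=dict(provenance or {}),
    )


def contour_slice(
    result: GridResult, fixed_angle: str, value: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Q surface over the two free angles with ``fixed_angle`` held at a node.

    Returns (axis1_values, axis2_values, Q matrix) where the matrix is
    indexed [axis1, axis2] with the free angles kept in (alpha, beta, gamma)
    order. ``value`` must be a grid node of the fixed angle.
    """
    names = ["alpha", "beta", "gamma"]
    if fixed_angle not in names:
        raise ValueError(f"fixed_angle must be one of {names}")
    axis = names.index(fixed_angle)
    vals = result.spec.axis_values(fixed_angle)
    hits = np.flatnonzero(np.isclose(vals, value, atol=1e-9))
    if len(hits) == 0:
        raise ValueError(f"{value} is not a grid node of {fixed_angle}")
    idx = int(hits[0])
    n = result.spec.n_per_angle
    cube = result.q.reshape(n, n, n)  # (alpha, beta, gamma)
    sliced = np.take(cube, idx, axis=axis)
    free = [a for a in names if a != fixed_angle]
    return result.spec.axis_values(free[0]), result.spec.axis_values(free[1]), sliced


def contour_slice_to_tsv(
    result: GridResult, fixed_angle: str, value: float
) -> str:
    """Tabular export of a contour slice (long format, one row per node)."""
    names = ["alpha", "beta", "gamma"]
    free = [a for a in names if a != fixed_angle]
    v1, v2, q = contour_slice(result, fixed_angle, value)
    a1, a2 = np.meshgrid(v1, v2, indexing="ij")
    df = pd.DataFrame({free[0]: a1.ravel(), free[1]: a2.ravel(), "Q": q.ravel()})
    df[fixed_angle] = value
    buf = io.StringIO()
    df[[*names, "Q"]].to_csv(buf, sep="\t", index=False)
    return buf.getvalue()


def export_top_models(
    result: GridResult, base_structure: StructureModel, n: int = 20
) -> tuple[str, pd.DataFrame]:
    """Write the n best orientations as a multi-model PDB plus a manifest.

    The manifest lists (model, alpha, beta, gamma, Q) with Q non-decreasing;
    gimbal-degenerate nodes (beta = 0) are flagged.
    """
    if n > len(result.q):
        raise ValueError(f"requested {n} models but grid has {len(result.q)} entries")
    top = result.top(n)
    blocks = []
    for i, row in enumerate(top.itertuples(index=False), start=1):
        rotated = rotate_domain(
            base_structure,
            result.domain,
            EulerOrientation(row.alpha, row.beta, row.gamma),
        )
        body = write_model_pdb(rotated)
        atoms = [
            ln
            for ln in body.splitlines()
            if ln.startswith(("ATOM", "HETATM", "TER"))
        ]
        blocks.append(f"MODEL     {i:4d}\n" + "\n".join(atoms) + "\nENDMDL")
    pdb_text = "\n".join(blocks) + "\nEND\n"
    manifest = top.reset_index(drop=True)
    manifest.insert(0, "model", np.arange(1, len(manifest) + 1))
    return pdb_text, manifest
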