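"""Synthetic two-domain datasets with known ground truth.

Generates stand-ins for every experimental input of the pipeline: a toy
two-domain methyl-site structure with a tagged domain and a lanthanide ion,
PCS tables produced from a planted susceptibility tensor (optionally with a
planted rigid rotation of the mobile domain for the "bound" state),
HETCOR-style peak lists, and predicted-shift tables for assignment tests.
Every generator is a pure function of its spec and seed and emits a
ground-truth sidecar sufficient to score recovery.

Geometry emulates the scale of a tagged two-domain protein whose tag was
positioned so that labeled sites in *both* domains sit within the ~30 Å
sphere of PCS influence: two clusters of Ala/Val methyls ~40 Å apart, the
ion above the tagged cluster on its mobile-domain-facing side (~25 Å from
the tagged centroid, ~32 Å from the mobile centroid). With the default
planted tensor (|Δχzz| ≈ 38×10⁻³² m³, the magnitude typical of Dy³⁺ tags)
every site then falls in a measurable PCS window (0.01–3 ppm), which is
asserted at generation time; clusters are redrawn a bounded number of
times if a site lands too close to the ion or on the tensor's magic-angle
null surface.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .assignment import Peak2D
from .pcs_model import ChiTensor, forward_pcs, PCS_TABLE_COLUMNS
from .structures import (
    DEFAULT_DOMAIN_RANGES,
    EulerOrientation,
    MethylSite,
    StructureModel,
    rotate_domain,
)

#: Default planted principal values, m³ (traceless; |Δχzz| at the Dy³⁺ scale).
DEFAULT_PRINCIPAL_VALUES = (-4.3e-32, -34.0e-32, 38.3e-32)

PCS_WINDOW = (0.01, 3.0)  # ppm, measurable-shift window asserted at generation
MIN_ION_SITE_DISTANCE = 5.0  # Å
MAX_REGENERATION_RETRIES = 50

_GEMINAL_OFFSET = 1.25  # Å, half the Cγ1–Cγ2 separation of a Val


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic generator.

    ``seed`` is mandatory: every stochastic output is a pure function of
    (spec, seed).
    """

    seed: int
    n_sites_per_domain: int = 12
    domain_separation: float = 40.0  # Å between cluster centroids
    cluster_radius: float = 12.0  # Å
    ion_offset: tuple[float, float, float] = (-15.0, 0.0, 20.0)  # Å from Ig2 centroid
    principal_values: tuple[float, float, float] = DEFAULT_PRINCIPAL_VALUES
    planted_rotation: EulerOrientation | None = None
    noise_sd: float = 0.01  # ppm
    decoy_para_peaks: int = 3

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_sites_per_domain < 5:
            raise ValueError("need at least 5 sites per domain to fit a tensor")
        if abs(sum(self.principal_values)) > 1e-12 * max(
            abs(v) for v in self.principal_values
        ):
            raise ValueError("planted principal values must sum to zero (traceless)")


def planted_tensor(spec: SyntheticSpec) -> ChiTensor:
    """Planted tensor: the spec's principal values in a seed-random frame."""
    rng = np.random.default_rng([spec.seed, 101])
    axes = _random_rotation(rng)
    t = axes @ np.diag(spec.principal_values) @ axes.T
    return ChiTensor.from_matrix(t)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    # QR of a Gaussian matrix, sign-fixed: Haar-uniform rotation
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 2] *= -1
    return q


def _sample_cluster(
    rng: np.random.Generator,
    n_sites: int,
    centroid: np.ndarray,
    radius: float,
    ion: np.ndarray,
    first_residue: int,
    domain: str,
) -> list[MethylSite]:
    """Random Ala/Val methyl sites in a sphere, outside the ion exclusion zone."""
    sites: list[MethylSite] = []
    residue = first_residue
    while len(sites) < n_sites:
        use_val = (n_sites - len(sites)) >= 2 and residue % 2 == first_residue % 2
        for _ in range(MAX_REGENERATION_RETRIES):
            # uniform point in the cluster sphere
            center = centroid + radius * rng.random() ** (1.0 / 3.0) * _unit(rng)
            if use_val:
                axis = _unit(rng)
                pos = [center + _GEMINAL_OFFSET * axis, center - _GEMINAL_OFFSET * axis]
            else:
                pos = [center]
            if all(np.linalg.norm(p - ion) >= MIN_ION_SITE_DISTANCE for p in pos):
                break
        else:
            raise RuntimeError("could not place sites outside the ion exclusion zone")
        if use_val:
            sites.append(
                MethylSite(residue, "Val", "Me1", domain, pos[0])
            )
            sites.append(
                MethylSite(residue, "Val", "Me2", domain, pos[1])
            )
        else:
            sites.append(MethylSite(residue, "Ala", "beta", domain, pos[0]))
        residue += 1
    return sites


def _unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.standard_normal(3)
    return v / np.linalg.norm(v)


def make_toy_structure(spec: SyntheticSpec) -> StructureModel:
    """Two rigid methyl clusters + pivot + ion; deterministic given the seed.

    Asserts that every site's noiseless PCS magnitude under the planted
    tensor lies in the measurable window (0.01–3 ppm), regenerating the
    clusters a bounded number of times if a site lands on the tensor's
    magic-angle null surface or too close to the ion.
    """
    tensor = planted_tensor(spec)
    ig2_centroid = np.zeros(3)
    ig1_centroid = np.array([-spec.domain_separation, 0.0, 0.0])
    pivot = ig1_centroid / 2.0
    ion = ig2_centroid + np.asarray(spec.ion_offset, dtype=float)

    ranges = DEFAULT_DOMAIN_RANGES
    for attempt in range(MAX_REGENERATION_RETRIES):
        rng = np.random.default_rng([spec.seed, 202, attempt])
        ig2 = _sample_cluster(
            rng, spec.n_sites_per_domain, ig2_centroid, spec.cluster_radius,
            ion, first_residue=ranges["Ig2"][0] + 4, domain="Ig2",
        )
        ig1 = _sample_cluster(
            rng, spec.n_sites_per_domain, ig1_centroid, spec.cluster_radius,
            ion, first_residue=ranges["Ig1"][0] + 4, domain="Ig1",
        )
        model = StructureModel(
            methyl_sites=tuple(ig1 + ig2),
            ion_position=ion,
            pivot_ca=pivot,
            domain_ranges=dict(ranges),
        )
        pcs = forward_pcs(tensor, ion, model.methyl_sites)
        lo, hi = PCS_WINDOW
        if np.all((np.abs(pcs) >= lo) & (np.abs(pcs) <= hi)):
            return model
    raise RuntimeError(
        f"no site arrangement inside the PCS window after {MAX_REGENERATION_RETRIES} tries"
    )


def simulate_pcs(
    structure: StructureModel,
    tensor: ChiTensor,
    noise_sd: float,
    seed: int,
    conditions: tuple[str, ...] = ("unbound", "bound"),
    planted_rotation: EulerOrientation | None = None,
    nuclei: tuple[str, ...] = ("C", "H"),
) -> tuple[pd.DataFrame, dict]:
    """PCS table for the requested conditions, plus a ground-truth sidecar.

    The "bound" condition first rotates the Ig1 domain by the planted
    rotation (the tagged domain, ion, and tensor are unchanged). Gaussian
    noise of sd ``noise_sd`` ppm is added independently per nucleus row.
    """
    rng = np.random.default_rng([seed, 303])
    rows = []
    noiseless: dict[str, list[float]] = {}
    for condition in conditions:
        model = structure
        if condition == "bound" and planted_rotation is not None:
            model = rotate_domain(structure, "Ig1", planted_rotation)
        values = forward_pcs(tensor, model.ion_position, model.methyl_sites)
        noiseless[condition] = values.tolist()
        for site, true_val in zip(model.methyl_sites, values):
            for nucleus in nuclei:
                rows.append(
                    {
                        "residue_number": site.residue_number,
                        "residue_type": site.residue_type,
                        "methyl_label": site.methyl_label,
                        "nucleus": nucleus,
                        "domain": site.domain,
                        "condition": condition,
                        "pcs_ppm": true_val + noise_sd * rng.standard_normal(),
                    }
                )
    table = pd.DataFrame(rows, columns=PCS_TABLE_COLUMNS)
    truth = {
        "tensor_v": tensor.v.tolist(),
        "tensor_convention": tensor.convention,
        "planted_rotation": (
            None if planted_rotation is None else list(planted_rotation.as_tuple())
        ),
        "noise_sd": noise_sd,
        "seed": seed,
        "noiseless_pcs": noiseless,
        "site_keys": [list(s.key) for s in structure.methyl_sites],
    }
    return table, truth


def default_dia_shifts(structure: StructureModel, seed: int) -> pd.DataFrame:
    """Plausible diamagnetic methyl shifts per site (¹³C 16–23, ¹H 0.7–1.4 ppm)."""
    rng = np.random.default_rng([seed, 404])
    rows = []
    for s in structure.methyl_sites:
        c_base = 17.5 if s.residue_type == "Ala" else 21.0
        rows.append(
            {
                "residue_number": s.residue_number,
                "methyl_label": s.methyl_label,
                "c_ppm": c_base + rng.uniform(-1.5, 1.5),
                "h_ppm": 1.05 + rng.uniform(-0.35, 0.35),
            }
        )
    return pd.DataFrame(rows)


def simulate_peaklists(
    structure: StructureModel,
    tensor: ChiTensor,
    dia_shifts: pd.DataFrame | None = None,
    noise_sd: float = 0.0,
    decoys: int = 0,
    bleach_fraction: float = 0.0,
    seed: int = 0,
) -> tuple[list[Peak2D], list[Peak2D], dict]:
    """Diamagnetic and paramagnetic peak lists with planted 1:1 PCSs.

    Each paramagnetic peak sits at the diamagnetic position plus the site's
    PCS in *both* dimensions (the 1:1 relation). ``decoys`` extra
    paramagnetic peaks appear at random positions with no diamagnetic
    counterpart; ``bleach_fraction`` of true paramagnetic peaks are deleted
    to emulate paramagnetic relaxation bleaching.
    """
    rng = np.random.default_rng([seed, 505])
    if dia_shifts is None:
        dia_shifts = default_dia_shifts(structure, seed)
    shift_map = {
        (int(r.residue_number), str(r.methyl_label)): (float(r.c_ppm), float(r.h_ppm))
        for r in dia_shifts.itertuples(index=False)
    }
    missing = [s.key for s in structure.methyl_sites if s.key not in shift_map]
    if missing:
        raise ValueError(f"dia_shifts does not cover sites: {missing}")

    pcs = forward_pcs(tensor, structure.ion_position, structure.methyl_sites)
    dia, para, truth_pairs = [], [], []
    for site, val in zip(structure.methyl_sites, pcs):
        c0, h0 = shift_map[site.key]
        label = f"{site.residue_type[0]}{site.residue_number}-{site.methyl_label}"
        dia.append(Peak2D(c0, h0, label=label, condition="diamagnetic"))
        para.append(
            Peak2D(
                c0 + val + noise_sd * rng.standard_normal(),
                h0 + val + noise_sd * rng.standard_normal(),
                label=label,
                condition="paramagnetic",
            )
        )
        truth_pairs.append({"label": label, "pcs_ppm": float(val)})

    n_bleach = int(round(bleach_fraction * len(para)))
    bleached = sorted(
        rng.choice(len(para), size=n_bleach, replace=False).tolist()
    ) if n_bleach else []
    para = [p for i, p in enumerate(para) if i not in set(bleached)]

    decoy_peaks = [
        Peak2D(
            rng.uniform(12.0, 24.0),
            rng.uniform(0.5, 1.6),
            label=f"decoy{i}",
            condition="paramagnetic",
        )
        for i in range(decoys)
    ]
    para = para + decoy_peaks
    truth = {
        "pairs": truth_pairs,
        "bleached_labels": [truth_pairs[i]["label"] for i in bleached],
        "n_decoys": decoys,
        "seed": seed,
    }
    return dia, para, truth


SHIFT_TYPES = ("Cg", "Hg", "Hb", "Ha")

#: Realistic Val shift centers (ppm) used by the assignment-problem generator.
_TRUE_SHIFT_WINDOWS = {
    "Cg": (19.0, 23.0),
    "Hg": (0.7, 1.3),
    "Hb": (1.7, 2.3),
    "Ha": (3.7, 4.6),
}


def simulate_assignment_problem(
    n_residues: int,
    prediction_error_sd: dict | float,
    seed: int,
    first_residue: int = 70,
) -> tuple[list, pd.DataFrame, dict]:
    """Spin systems, a predicted-shift table, and the true peak→residue map.

    True per-residue shifts are drawn uniformly in realistic windows;
    observed spin systems carry the true shifts, while predictions carry
    independent Gaussian error per shift type (a flat sd may be given for
    all types). The sidecar maps peak label → residue number.
    """
    from .assignment import SpinSystem

    if not isinstance(prediction_error_sd, dict):
        prediction_error_sd = {t: float(prediction_error_sd) for t in SHIFT_TYPES}
    rng = np.random.default_rng([seed, 606])
    residues = list(range(first_residue, first_residue + n_residues))
    true_shifts = {
        r: {t: rng.uniform(*_TRUE_SHIFT_WINDOWS[t]) for t in SHIFT_TYPES}
        for r in residues
    }
    spin_systems = [
        SpinSystem(label=f"p{r}", shifts=dict(true_shifts[r])) for r in residues
    ]
    pred_rows = [
        {
            "residue_number": r,
            "type": t,
            "predicted_ppm": true_shifts[r][t]
            + prediction_error_sd[t] * rng.standard_normal(),
        }
        for r in residues
        for t in SHIFT_TYPES
    ]
    predictions = pd.DataFrame(pred_rows)
    truth = {"mapping": {f"p{r}": r for r in residues}, "seed": seed}
    return spin_systems, predictions, truth


def write_truth_sidecar(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2)
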