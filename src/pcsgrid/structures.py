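"""Structural models: labeled methyl sites, rigid-body rotations, superposition.

The pipeline works on a reduced representation of a two-domain protein: the
methyl carbons of Ala (Cβ) and Val (Cγ1/Cγ2), a modelled lanthanide ion, and
the Cα of a pivot residue in the interdomain linker. Domains are assigned
from residue-number ranges.
"""
from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field, replace

import gemmi
import numpy as np

logger = logging.getLogger(__name__)

#: Default domain ranges (inclusive residue intervals, Uniprot numbering):
#: Ig1 up to the linker residue, Ig2 after it.
DEFAULT_DOMAIN_RANGES: dict[str, tuple[int, int]] = {
    "Ig1": (61, 165),
    "Ig2": (166, 266),
}

#: Default pivot residue for interdomain rotations: the linker Cα.
DEFAULT_PIVOT_RESIDUE = 165

#: Elements accepted as the paramagnetic ion when scanning HETATM records.
LANTHANIDE_ELEMENTS = frozenset(
    "LA CE PR ND PM SM EU GD TB DY HO ER TM YB LU".split()
)

VALID_METHYL_LABELS = ("Me1", "Me2", "beta")
VALID_RESIDUE_TYPES = ("Ala", "Val")

# methyl carbon atom name <-> label, per residue type
_ATOM_TO_LABEL = {("ALA", "CB"): "beta", ("VAL", "CG1"): "Me1", ("VAL", "CG2"): "Me2"}
_LABEL_TO_ATOM = {v: k for k, v in _ATOM_TO_LABEL.items()}


@dataclass(frozen=True)
class MethylSite:
    """A labeled methyl carbon position.

    Parameters
    ----------
    residue_number : int
        Residue number (Uniprot convention, as in the source PDB).
    residue_type : str
        ``"Ala"`` or ``"Val"``.
    methyl_label : str
        ``"beta"`` for Ala Cβ, ``"Me1"``/``"Me2"`` for Val Cγ1/Cγ2.
    domain : str
        Domain tag from the configured residue-range map (e.g. ``"Ig1"``).
    position : (3,) ndarray
        Cartesian coordinates in Å.
    """

    residue_number: int
    residue_type: str
    methyl_label: str
    domain: str
    position: np.ndarray

    def __post_init__(self):
        if self.residue_type not in VALID_RESIDUE_TYPES:
            raise ValueError(f"unknown residue type {self.residue_type!r}")
        if self.methyl_label not in VALID_METHYL_LABELS:
            raise ValueError(f"unknown methyl label {self.methyl_label!r}")
        if self.residue_type == "Ala" and self.methyl_label != "beta":
            raise ValueError("Ala sites must carry the beta label")
        if self.residue_type == "Val" and self.methyl_label == "beta":
            raise ValueError("Val sites must carry Me1 or Me2")
        pos = np.asarray(self.position, dtype=float)
        if pos.shape != (3,) or not np.all(np.isfinite(pos)):
            raise ValueError("position must be a finite 3-vector")
        object.__setattr__(self, "position", pos)

    @property
    def key(self) -> tuple[int, str]:
        """(residue_number, methyl_label) — the site identity used for matching."""
        return (self.residue_number, self.methyl_label)


@dataclass(frozen=True)
class EulerOrientation:
    """ZXZ Euler angles in degrees, intrinsic: R = Rz(alpha)·Rx(beta)·Rz(gamma)."""

    alpha: float
    beta: float
    gamma: float

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha, self.beta, self.gamma)


@dataclass(frozen=True)
class StructureModel:
    """Reduced structural model: methyl sites + ion + pivot + domain map."""

    methyl_sites: tuple[MethylSite, ...]
    ion_position: np.ndarray
    pivot_ca: np.ndarray
    domain_ranges: dict[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_DOMAIN_RANGES)
    )

    def __post_init__(self):
        object.__setattr__(self, "methyl_sites", tuple(self.methyl_sites))
        for name in ("ion_position", "pivot_ca"):
            v = np.asarray(getattr(self, name), dtype=float)
            if v.shape != (3,) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite 3-vector")
            object.__setattr__(self, name, v)

    def sites_in_domain(self, domain: str) -> tuple[MethylSite, ...]:
        return tuple(s for s in self.methyl_sites if s.domain == domain)

    def site_map(self) -> dict[tuple[int, str], MethylSite]:
        return {s.key: s for s in self.methyl_sites}

    def positions(self) -> np.ndarray:
        return np.array([s.position for s in self.methyl_sites])


def _domain_of(residue_number: int, domain_ranges: dict[str, tuple[int, int]]) -> str | None:
    for name, (lo, hi) in domain_ranges.items():
        if lo <= residue_number <= hi:
            return name
    return None


def load_structure(
    pdb_text: str,
    domain_ranges: dict[str, tuple[int, int]] | None = None,
    pivot_residue: int = DEFAULT_PIVOT_RESIDUE,
    ion_source=None,
    required_domains: tuple[str, ...] = (),
) -> StructureModel:
    """Parse a PDB string into a :class:`StructureModel`.

    Extracts Ala Cβ and Val Cγ1/Cγ2 methyl carbons, the pivot Cα, and the
    lanthanide ion. ``ion_source`` is either ``None``/an atom-name selector
    (scan HETATMs for a lanthanide element, optionally restricted to that
    atom name) or explicit coordinates (any 3-sequence). Residues outside
    every domain range are dropped with a logged warning.

    Raises
    ------
    ValueError
        If the pivot Cα is missing, the ion is absent or ambiguous, or a
        required domain has no methyl sites.
    """
    domain_ranges = dict(domain_ranges or DEFAULT_DOMAIN_RANGES)
    st = gemmi.read_pdb_string(pdb_text)
    if len(st) == 0:
        raise ValueError("no models in PDB input")
    model = st[0]

    sites: list[MethylSite] = []
    pivot_ca = None
    ion_candidates: list[np.ndarray] = []
    explicit_ion = ion_source is not None and not isinstance(ion_source, str)

    for chain in model:
        for res in chain:
            seqid = res.seqid.num
            het = res.het_flag == "H"
            if het:
                for atom in res:
                    elem = atom.element.name.upper()
                    if elem in LANTHANIDE_ELEMENTS and (
                        not isinstance(ion_source, str)
                        or atom.name.strip().upper() == ion_source.strip().upper()
                    ):
                        ion_candidates.append(np.array(atom.pos.tolist()))
                continue
            if seqid == pivot_residue:
                ca = res.find_atom("CA", "*")
                if ca is not None:
                    pivot_ca = np.array(ca.pos.tolist())
            if res.name not in ("ALA", "VAL"):
                continue
            domain = _domain_of(seqid, domain_ranges)
            if domain is None:
                logger.warning(
                    "residue %s %d outside all domain ranges; dropped", res.name, seqid
                )
                continue
            for atom in res:
                label = _ATOM_TO_LABEL.get((res.name, atom.name.strip()))
                if label is None:
                    continue
                sites.append(
                    MethylSite(
                        residue_number=seqid,
                        residue_type="Ala" if res.name == "ALA" else "Val",
                        methyl_label=label,
                        domain=domain,
                        position=np.array(atom.pos.tolist()),
                    )
                )

    if pivot_ca is None:
        raise ValueError(f"pivot CA not found for residue {pivot_residue}")

    if explicit_ion:
        ion_position = np.asarray(ion_source, dtype=float)
    else:
        if len(ion_candidates) == 0:
            raise ValueError("no lanthanide ion found in PDB and no coordinates given")
        if len(ion_candidates) > 1:
            raise ValueError(
                f"ambiguous ion: {len(ion_candidates)} lanthanide HETATM candidates"
            )
        ion_position = ion_candidates[0]

    for dom in required_domains:
        if not any(s.domain == dom for s in sites):
            raise ValueError(f"no methyl sites found in required domain {dom!r}")

    return StructureModel(
        methyl_sites=tuple(sites),
        ion_position=ion_position,
        pivot_ca=pivot_ca,
        domain_ranges=domain_ranges,
    )


def euler_to_matrix(orientation: EulerOrientation) -> np.ndarray:
    """Rotation matrix for ZXZ intrinsic Euler angles (degrees), acting on
    column vectors: R = Rz(alpha)·Rx(beta)·Rz(gamma)."""
    a, b, g = np.deg2rad(orientation.as_tuple())
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    rz_a = np.array([[ca, -sa, 0.0], [sa, ca, 0.0], [0.0, 0.0, 1.0]])
    rx_b = np.array([[1.0, 0.0, 0.0], [0.0, cb, -sb], [0.0, sb, cb]])
    rz_g = np.array([[cg, -sg, 0.0], [sg, cg, 0.0], [0.0, 0.0, 1.0]])
    return rz_a @ rx_b @ rz_g


def rotate_domain(
    structure: StructureModel, domain: str, orientation: EulerOrientation
) -> StructureModel:
    """Rotate every site of ``domain`` about the pivot Cα; all else is fixed.

    Sites map as x -> pivot + R·(x − pivot). The ion, pivot, and other
    domains are unchanged.
    """
    if not any(s.domain == domain for s in structure.methyl_sites):
        raise ValueError(f"unknown or empty domain {domain!r}")
    if orientation.as_tuple() == (0.0, 0.0, 0.0):
        return structure
    rot = euler_to_matrix(orientation)
    pivot = structure.pivot_ca
    new_sites = tuple(
        replace(s, position=pivot + rot @ (s.position - pivot))
        if s.domain == domain
        else s
        for s in structure.methyl_sites
    )
    return replace(structure, methyl_sites=new_sites)


def superpose_by_domain(
    mobile: StructureModel, reference: StructureModel, domain: str
) -> tuple[StructureModel, float]:
    """Least-squares rigid superposition of ``mobile`` onto ``reference``
    using the common sites of one domain (Kabsch, no scaling).

    Sites are matched by (residue_number, methyl_label); the fitted
    rotation + translation is applied to all coordinates including ion and
    pivot. Returns the transformed model and the RMSD (Å) over the matched
    sites.
    """
    mob_map = {s.key: s for s in mobile.sites_in_domain(domain)}
    ref_map = {s.key: s for s in reference.sites_in_domain(domain)}
    common = sorted(mob_map.keys() & ref_map.keys())
    if len(common) < 3:
        raise ValueError(
            f"need >=3 common sites in domain {domain!r}, found {len(common)}"
        )
    x = np.array([mob_map[k].position for k in common])
    y = np.array([ref_map[k].position for k in common])
    xc, yc = x.mean(axis=0), y.mean(axis=0)
    # Kabsch via SVD of the covariance, with proper-rotation correction
    h = (x - xc).T @ (y - yc)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T

    def transform(p: np.ndarray) -> np.ndarray:
        return rot @ (p - xc) + yc

    new_sites = tuple(replace(s, position=transform(s.position)) for s in mobile.methyl_sites)
    moved = replace(
        mobile,
        methyl_sites=new_sites,
        ion_position=transform(mobile.ion_position),
        pivot_ca=transform(mobile.pivot_ca),
    )
    fitted = np.array([transform(mob_map[k].position) for k in common])
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - y) ** 2, axis=1))))
    return moved, rmsd


def write_model_pdb(
    structure: StructureModel,
    pivot_residue: int = DEFAULT_PIVOT_RESIDUE,
    ion_element: str = "DY",
) -> str:
    """Serialize a :class:`StructureModel` as PDB text.

    Methyl carbons are written as ATOM records of ALA/VAL residues (one
    residue may carry two Val methyls), the ion as a HETATM, and the pivot
    Cα as a GLY CA at ``pivot_residue`` so a round trip through
    :func:`load_structure` recovers the model. Coordinates keep PDB
    precision (1e-3 Å).
    """
    st = gemmi.Structure()
    st.name = "model"
    model = gemmi.Model("1")
    chain = gemmi.Chain("A")

    by_res: dict[int, list[MethylSite]] = {}
    for s in structure.methyl_sites:
        by_res.setdefault(s.residue_number, []).append(s)

    used = set(by_res)
    pivot_num = pivot_residue
    if pivot_num in used:
        pivot_num = int(max(used) + 1)
        logger.warning(
            "pivot residue %d holds a methyl site; writing pivot CA as residue %d",
            pivot_residue, pivot_num,
        )

    for num in sorted(by_res):
        sites = by_res[num]
        res = gemmi.Residue()
        res.name = "ALA" if sites[0].residue_type == "Ala" else "VAL"
        res.seqid = gemmi.SeqId(num, " ")
        for s in sites:
            _, atom_name = _LABEL_TO_ATOM[s.methyl_label]
            atom = gemmi.Atom()
            atom.name = atom_name
            atom.element = gemmi.Element("C")
            atom.pos = gemmi.Position(*s.position)
            res.add_atom(atom)
        chain.add_residue(res)

    piv = gemmi.Residue()
    piv.name = "GLY"
    piv.seqid = gemmi.SeqId(pivot_num, " ")
    ca = gemmi.Atom()
    ca.name = "CA"
    ca.element = gemmi.Element("C")
    ca.pos = gemmi.Position(*structure.pivot_ca)
    piv.add_atom(ca)
    chain.add_residue(piv)

    ion_res = gemmi.Residue()
    ion_res.name = ion_element
    ion_res.seqid = gemmi.SeqId(int(max(used | {pivot_num}) + 1), " ")
    ion_res.het_flag = "H"
    ion = gemmi.Atom()
    ion.name = ion_element
    ion.element = gemmi.Element(ion_element.capitalize())
    ion.pos = gemmi.Position(*structure.ion_position)
    ion_res.add_atom(ion)
    chain.add_residue(ion_res)

    model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    return st.make_pdb_string(gemmi.PdbWriteOptions(minimal=True))
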