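"""Deterministic toy fixtures: 7-TM receptors, ligands, screening tables.

Everything downstream of real structure/docking inputs can be exercised
on these generators, so the whole analysis stack is testable offline.

:func:`make_toy_complex` builds an idealised 7-helix bundle (standard
alpha-helix C-alpha geometry: 2.3 A helix radius, 1.5 A rise, 100 deg per
residue) on a ring, with coarse side chains made of real PDB atom names
so the interaction-fingerprint typing tables apply unmodified.  One
residue per helix lines the orthosteric pocket near the extracellular
end, and a ligand is posed so that each pocket residue realises its
designed interaction (salt bridges to Asp/Arg, H-bonds to Ser/Asn,
an aromatic stack with Phe, a hydrophobic contact with Val) at canonical
distances.  That clean geometry is the "planted" pocket optimum the
refinement orchestrator should recover after perturbation.

:func:`make_screen_table` draws repeat docking scores from
class-conditional normal distributions (lower = better), so the expected
screening enrichment is controlled by the class-mean separation.

All generators are pure functions of (spec, seed); emitted PDB text uses
fixed 3-decimal coordinates, so file hashes are reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import biotite.structure as struc

from .core_model import Complex, TopologyAnnotation
from .errors import IdError, SpecError
from .vs_metrics import ScreenTable

__all__ = [
    "ToyReceptorSpec",
    "ScreenSpec",
    "make_toy_complex",
    "make_screen_table",
    "perturb_complex",
    "designed_contact_wells",
]


# ---------------------------------------------------------------------------
# Toy receptor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ToyReceptorSpec:
    """Geometry of the generated 7-TM toy receptor."""

    residues_per_helix: int = 12
    ring_radius: float = 11.0       # bundle axis to helix axis, A
    helix_radius: float = 2.3       # C-alpha helix radius, A
    rise: float = 1.5               # A per residue
    twist_deg: float = 100.0        # deg per residue
    anchor_depth: int = 5           # BW anchor, residues from the EC end
    loop_len: int = 2               # ECL1/3, ICL1-3, termini length
    ecl2_len: int = 5               # ECL2 length (cysteine at its middle)
    seed: int = 0

    n_helices: int = field(default=7, init=False)


# pocket-lining residue per helix: (index from the extracellular end, type).
# The Phe sits one turn higher so its ring stacks with the ligand ring above
# the polar tier instead of crowding it.
_POCKET_SITES = {1: (1, "ALA"), 2: (1, "ASN"), 3: (1, "ASP"), 4: (1, "VAL"),
                 5: (1, "SER"), 6: (0, "PHE"), 7: (1, "ARG")}
_FILLER_TYPES = ("ALA", "LEU", "VAL", "ALA")

_ELEMENT_OF = {
    "CA": "C", "CB": "C", "CG": "C", "CG1": "C", "CG2": "C", "CD": "C",
    "CD1": "C", "CD2": "C", "CE1": "C", "CE2": "C", "CZ": "C",
    "OG": "O", "OD1": "O", "OE1": "O",
    "ND2": "N", "NE": "N", "NH1": "N", "NH2": "N",
    "OD2": "O", "SG": "S",
}


def _deg(x):
    return math.radians(x)


class _Builder:
    def __init__(self):
        self.rows = []  # (res_id, res_name, atom_name, element, xyz, charge)

    def atom(self, res_id, res_name, atom_name, xyz, charge=0, element=None):
        el = element or _ELEMENT_OF.get(atom_name, atom_name[0])
        self.rows.append((res_id, res_name, atom_name, el,
                          np.asarray(xyz, float), charge))

    def to_array(self, chain="A", hetero=False) -> struc.AtomArray:
        n = len(self.rows)
        arr = struc.AtomArray(n)
        arr.coord = np.round(np.array([r[4] for r in self.rows]), 3)
        arr.chain_id = np.array([chain] * n)
        arr.res_id = np.array([r[0] for r in self.rows])
        arr.res_name = np.array([r[1] for r in self.rows])
        arr.atom_name = np.array([r[2] for r in self.rows])
        arr.element = np.array([r[3] for r in self.rows])
        arr.hetero = np.array([hetero] * n)
        arr.set_annotation("occupancy", np.ones(n))
        arr.set_annotation("charge", np.array([r[5] for r in self.rows]))
        return arr


def _sidechain_atoms(res_name: str, ca: np.ndarray, direction: np.ndarray,
                     perp: np.ndarray):
    """Coarse side chain along ``direction`` with real atom names.

    Distances are idealised reach values chosen so pocket interactions
    land at canonical geometry; they are not rotamer-accurate.
    """
    d = direction
    out = []
    if res_name == "GLY":
        return out
    out.append(("CB", ca + 1.5 * d))
    if res_name == "ALA":
        pass
    elif res_name == "VAL":
        out.append(("CG1", ca + 2.6 * d))
        out.append(("CG2", ca + 2.2 * d + 0.9 * perp))
    elif res_name == "LEU":
        out.append(("CG", ca + 2.4 * d))
        out.append(("CD1", ca + 3.3 * d))
        out.append(("CD2", ca + 3.0 * d + 1.0 * perp))
    elif res_name == "SER":
        out.append(("OG", ca + 2.9 * d))
    elif res_name == "CYS":
        out.append(("SG", ca + 2.8 * d))
    elif res_name == "ASN":
        out.append(("CG", ca + 2.6 * d))
        out.append(("OD1", ca + 3.7 * d + 0.6 * perp))
        out.append(("ND2", ca + 3.7 * d - 0.6 * perp))
    elif res_name == "ASP":
        out.append(("CG", ca + 2.6 * d))
        out.append(("OD1", ca + 3.7 * d + 1.0 * perp))
        out.append(("OD2", ca + 3.7 * d - 1.0 * perp))
    elif res_name == "ARG":
        out.append(("CG", ca + 2.2 * d))
        out.append(("CD", ca + 2.8 * d))
        out.append(("NE", ca + 3.1 * d + 0.4 * perp))
        out.append(("CZ", ca + 3.4 * d))
        out.append(("NH1", ca + 3.9 * d + 1.0 * perp))
        out.append(("NH2", ca + 3.9 * d - 1.0 * perp))
    elif res_name == "PHE":
        centroid = ca + 2.6 * d
        out.append(("CG", None))  # placeholder, replaced below
        # hexagonal ring in the plane normal to ``direction``
        up = np.array([0.0, 0.0, 1.0])
        names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
        out = out[:-1]
        for k, name in enumerate(names):
            ang = _deg(60 * k)
            pos = centroid + 1.39 * (math.cos(ang) * perp + math.sin(ang) * up)
            out.append((name, pos))
    else:
        raise SpecError(f"unsupported toy residue type {res_name!r}")
    return out


def make_toy_complex(
    spec: ToyReceptorSpec = ToyReceptorSpec(),
) -> tuple[Complex, TopologyAnnotation, dict[str, str]]:
    """Generate a 7-TM toy receptor with a posed ligand.

    Returns the complex, its topology annotation and the
    Ballesteros-Weinstein anchor map.  Raises :class:`SpecError` for
    geometrically infeasible parameters (overlapping helices,
    non-positive rise, helices too short to hold the anchor).
    """
    n = spec.residues_per_helix
    if n < spec.anchor_depth + 2:
        raise SpecError("helix too short for the anchor depth")
    if spec.rise <= 0 or spec.helix_radius <= 0:
        raise SpecError("rise and helix radius must be positive")
    min_sep = 2 * spec.ring_radius * math.sin(math.pi / 7)
    if min_sep <= 2 * spec.helix_radius + 1.0:
        raise SpecError(
            f"helix spacing {min_sep:.2f} A would overlap helices "
            f"(radius {spec.helix_radius} A)"
        )

    z_top = 0.0
    phis = [_deg((k - 1) * 360.0 / 7) for k in range(1, 8)]

    # --- helix C-alpha traces, indexed from the extracellular end -------
    ca = {}          # (helix, i_from_top) -> xyz
    inward = {}      # unit vector from helix inner face toward bundle axis
    for k in range(1, 8):
        phi = phis[k - 1]
        axis = np.array([spec.ring_radius * math.cos(phi),
                         spec.ring_radius * math.sin(phi), 0.0])
        inw = -np.array([math.cos(phi), math.sin(phi), 0.0])
        inward[k] = inw
        # phase such that residue i=1 faces the bundle axis
        phase = math.atan2(inw[1], inw[0]) - _deg(spec.twist_deg)
        for i in range(n):
            theta = phase + _deg(spec.twist_deg) * i
            ca[(k, i)] = axis + np.array(
                [spec.helix_radius * math.cos(theta),
                 spec.helix_radius * math.sin(theta),
                 z_top - spec.rise * i]
            )

    # --- sequence layout -------------------------------------------------
    loops = {"NTERM": spec.loop_len, "ICL1": spec.loop_len,
             "ECL1": spec.loop_len, "ICL2": spec.loop_len,
             "ECL2": spec.ecl2_len, "ICL3": spec.loop_len,
             "ECL3": spec.loop_len, "CTERM": spec.loop_len}
    order = ["NTERM", "TM1", "ICL1", "TM2", "ECL1", "TM3", "ICL2", "TM4",
             "ECL2", "TM5", "ICL3", "TM6", "ECL3", "TM7", "CTERM"]
    segments: dict[str, tuple[int, int]] = {}
    res_id = 1
    for label in order:
        length = n if label.startswith("TM") else loops[label]
        segments[label] = (res_id, res_id + length - 1)
        res_id += length
    ecl2_start = segments["ECL2"][0]
    ecl2_cys = ecl2_start + spec.ecl2_len // 2
    topology = TopologyAnnotation(segments=segments, ecl2_cysteine=ecl2_cys)

    # residue id <-> (helix, i_from_top): odd helices run EC->IC in
    # sequence, even helices IC->EC
    def helix_res_id(k: int, i_from_top: int) -> int:
        start, end = segments[f"TM{k}"]
        return start + i_from_top if k % 2 == 1 else end - i_from_top

    bw_map = {}
    for k, bw in enumerate(
        ("1.48", "2.51", "3.38", "4.51", "5.50", "6.43", "7.45"), start=1
    ):
        bw_map[bw] = f"A:{helix_res_id(k, spec.anchor_depth)}"

    # --- build receptor atoms -------------------------------------------
    b = _Builder()
    filler_rng = np.random.default_rng(spec.seed)  # reserved; layout is fixed

    def tm_residue(k: int, i: int):
        rid = helix_res_id(k, i)
        pos = ca[(k, i)]
        site_i, site_type = _POCKET_SITES[k]
        if i == site_i:
            res_name = site_type
            direction = inward[k]
        else:
            res_name = _FILLER_TYPES[(k + i) % len(_FILLER_TYPES)]
            out_dir = pos - np.array(
                [spec.ring_radius * math.cos(phis[k - 1]),
                 spec.ring_radius * math.sin(phis[k - 1]), pos[2]]
            )
            direction = out_dir / np.linalg.norm(out_dir)
        perp = np.array([-direction[1], direction[0], 0.0])
        if np.linalg.norm(perp) < 1e-9:
            perp = np.array([1.0, 0.0, 0.0])
        perp /= np.linalg.norm(perp)
        return rid, res_name, pos, direction, perp

    # collect all residues in sequence order
    residue_records = {}
    for k in range(1, 8):
        for i in range(n):
            rid, res_name, pos, direction, perp = tm_residue(k, i)
            atoms = [("CA", pos)] + _sidechain_atoms(res_name, pos, direction,
                                                     perp)
            residue_records[rid] = (res_name, atoms)

    # loops: simple arcs between flanking helix ends (or stubs for termini)
    def loop_arc(label: str):
        start, end = segments[label]
        length = end - start + 1
        ec = label.startswith(("ECL", "NTERM"))
        bump = 2.5 if ec else -2.5
        prev_label = order[order.index(label) - 1] if order.index(label) else None
        next_label = (order[order.index(label) + 1]
                      if order.index(label) + 1 < len(order) else None)

        def seg_endpoint(seg_label, at_start):
            s, e = segments[seg_label]
            rid = s if at_start else e
            k = int(seg_label[2:])
            i = rid - s if k % 2 == 1 else e - rid
            return ca[(k, i)]

        if prev_label and prev_label.startswith("TM"):
            p = seg_endpoint(prev_label, at_start=False)
        else:
            p = None
        if next_label and next_label.startswith("TM"):
            q = seg_endpoint(next_label, at_start=True)
        else:
            q = None
        if p is None:
            p = q + np.array([3.0, 0.0, bump])
        if q is None:
            q = p + np.array([3.0, 0.0, bump])
        for idx, rid in enumerate(range(start, end + 1)):
            t = (idx + 1) / (length + 1)
            pos = (1 - t) * p + t * q
            pos = pos + np.array([0.0, 0.0, bump * math.sin(math.pi * t)])
            res_name = "CYS" if (label == "ECL2" and rid == ecl2_cys) else "GLY"
            direction = np.array([0.0, 0.0, 1.0 if ec else -1.0])
            perp = np.array([1.0, 0.0, 0.0])
            atoms = [("CA", pos)] + _sidechain_atoms(res_name, pos, direction,
                                                     perp)
            residue_records[rid] = (res_name, atoms)

    for label in order:
        if not label.startswith("TM"):
            loop_arc(label)

    for rid in sorted(residue_records):
        res_name, atoms = residue_records[rid]
        for atom_name, pos in atoms:
            b.atom(rid, res_name, atom_name, pos)
    receptor = b.to_array(chain="A", hetero=False)

    # --- ligand -----------------------------------------------------------
    zp = z_top - spec.rise * 1  # polar tier (C-alpha z of residues at i=1)
    r_in = spec.ring_radius - spec.helix_radius

    def radial(r, k, z=None):
        phi = phis[k - 1]
        return np.array([r * math.cos(phi), r * math.sin(phi),
                         zp if z is None else z])

    lb = _Builder()
    # benzene ring one tier above the polar plane, stacked edge-on with the
    # TM6 Phe ring (centroid-centroid 4.3 A, interplanar angle 90 deg)
    phe_rid = helix_res_id(6, _POCKET_SITES[6][0])
    phe_names = ("CG", "CD1", "CE1", "CZ", "CE2", "CD2")
    phe_atoms = np.array(
        [pos for an, pos in residue_records[phe_rid][1] if an in phe_names]
    )
    phe_centroid = phe_atoms.mean(axis=0)
    z_ring = z_top + spec.rise
    dz = z_ring - phe_centroid[2]
    dir_h = -np.array([phe_centroid[0], phe_centroid[1], 0.0])
    dir_h /= np.linalg.norm(dir_h)
    ring_centroid = (
        phe_centroid + math.sqrt(4.3 ** 2 - dz ** 2) * dir_h
        + np.array([0.0, 0.0, dz])
    )
    for j in range(6):
        ang = _deg(60 * j)
        pos = ring_centroid + 1.39 * np.array(
            [math.cos(ang), math.sin(ang), 0.0]
        )
        lb.atom(1, "LIG", f"C{j + 1}", pos)
    # cationic amine 2.9 A inward of the Asp carboxylate midpoint (TM3)
    lb.atom(1, "LIG", "N1", radial(r_in - 3.7 - 2.9, 3), charge=+1)
    # hydroxyl acceptor 3.0 A inward of the Ser OG (TM5)
    lb.atom(1, "LIG", "O1", radial(r_in - 2.9 - 3.0, 5))
    # anionic oxygen 2.9 A inward of the Arg NH midpoint (TM7)
    lb.atom(1, "LIG", "O2", radial(r_in - 3.9 - 2.9, 7), charge=-1)
    # acceptor facing the Asn amide (TM2)
    lb.atom(1, "LIG", "O3", radial(r_in - 3.7 - 3.2, 2))
    # methyl probing the Val hydrophobic wall (TM4)
    lb.atom(1, "LIG", "C7", radial(r_in - 2.6 - 3.0, 4))
    ligand = lb.to_array(chain="L", hetero=True)
    ligand.res_id[:] = 900

    cpx = Complex(
        receptor=receptor,
        ligand=ligand,
        metadata={"generator": "make_toy_complex", "seed": spec.seed},
    )
    return cpx, topology, bw_map


def designed_contact_wells(cpx: Complex, pocket, n_partners: int = 6) -> list:
    """Contact wells encoding the complex's CURRENT pocket geometry.

    For every selected side-chain heavy atom of each pocket residue (up
    to three: base, middle and tip of the side chain), records Gaussian
    wells to its ``n_partners`` nearest ligand heavy atoms at the current
    distances, weights split evenly within a residue.  Multiple partners
    in different directions pin each residue in full 3D — a single
    distance constraint would leave motion on the sphere around the
    partner invisible.  Feeding these wells to the toy dock makes the
    present geometry the score optimum: the planted target of the
    refinement recovery tests.
    """
    from .core_model import atom_res_keys

    keys = atom_res_keys(cpx.receptor)
    lig = cpx.ligand
    lig_heavy = lig.element != "H"
    lig_names = lig.atom_name[lig_heavy]
    lig_xyz = lig.coord[lig_heavy]
    wells = []
    for key in pocket.residues:
        res = cpx.receptor[keys == key]
        side = [(an, xyz) for an, xyz in zip(res.atom_name, res.coord)
                if an != "CA"]
        if not side:
            continue
        if len(side) > 3:
            side = [side[0], side[len(side) // 2], side[-1]]
        k = min(n_partners, len(lig_xyz))
        w = 1.0 / (len(side) * k)
        for an, xyz in side:
            d = np.linalg.norm(lig_xyz - xyz, axis=1)
            for j in np.argsort(d)[:k]:
                wells.append(
                    (key, str(an), str(lig_names[j]), float(d[j]), w)
                )
    return wells


# ---------------------------------------------------------------------------
# Perturbation
# ---------------------------------------------------------------------------

def perturb_complex(
    cpx: Complex, region, magnitude: float, seed: int
) -> Complex:
    """Rigid per-residue random displacement of the named region.

    Each residue in ``region`` is displaced by an independent random
    vector of norm <= ``magnitude`` (uniform direction, uniform radius),
    so the region's coordinate RMSD is bounded by ``magnitude``.  All
    other residues and the ligand are bit-identical to the input.
    """
    if magnitude < 0:
        raise SpecError("magnitude must be non-negative")
    region = list(region)
    present = set(cpx.residue_keys)
    unknown = [r for r in region if r not in present]
    if unknown:
        raise IdError(f"unknown residues in region: {unknown[:5]}")
    out = cpx.copy()
    if magnitude == 0 or not region:
        return out
    rng = np.random.default_rng(seed)
    from .core_model import atom_res_keys

    keys = atom_res_keys(out.receptor)
    for key in region:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        v *= magnitude * rng.uniform()
        out.receptor.coord[keys == key] += v
    return out


# ---------------------------------------------------------------------------
# Screening tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScreenSpec:
    """Class-conditional score model for a labeled screening library.

    Scores are docking-style (lower = more favorable), drawn i.i.d. per
    repeat from normal distributions.  The default 6-unit active/decoy
    mean gap with sd 3 yields a clearly-better-than-random but imperfect
    screen; set ``decoy_mean == active means`` for a null screen or give
    actives a disjoint support for a perfect one.
    """

    n_agonists: int = 40
    n_inhibitors: int = 40
    n_decoys: int = 920
    agonist_mean: float = -32.0
    inhibitor_mean: float = -32.0
    decoy_mean: float = -26.0
    sd: float = 3.0
    n_repeats: int = 3
    n_chemotypes: int = 4
    seed: int = 0


def make_screen_table(spec: ScreenSpec) -> ScreenTable:
    """Generate a labeled score table from a :class:`ScreenSpec`."""
    for name in ("n_agonists", "n_inhibitors", "n_decoys"):
        if getattr(spec, name) < 0:
            raise SpecError(f"{name} must be non-negative")
    if spec.n_repeats < 1:
        raise SpecError("n_repeats must be >= 1")
    if spec.n_agonists + spec.n_inhibitors + spec.n_decoys == 0:
        raise SpecError("empty library")
    rng = np.random.default_rng(spec.seed)

    rows = []
    counter = 0

    def add(n, role, pharm, mean):
        nonlocal counter
        for _ in range(n):
            cid = f"C{counter:05d}"
            counter += 1
            chemo = ""
            if role == "active" and spec.n_chemotypes > 0:
                chemo = "ct%d" % (rng.integers(spec.n_chemotypes) + 1)
            scores = rng.normal(mean, spec.sd, size=spec.n_repeats)
            rows.append((cid, role, pharm, chemo, *np.round(scores, 4)))

    add(spec.n_agonists, "active", "agonist", spec.agonist_mean)
    add(spec.n_inhibitors, "active", "inhibitor", spec.inhibitor_mean)
    add(spec.n_decoys, "decoy", "none", spec.decoy_mean)

    cols = ["id", "role", "pharmacology", "chemotype"] + [
        f"score_{k + 1}" for k in range(spec.n_repeats)
    ]
    df = pd.DataFrame(rows, columns=cols)
    return ScreenTable(df, higher_better=False)
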