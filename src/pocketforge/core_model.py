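"""Structural substrate: complexes, binding pockets, receptor regions.

A :class:`Complex` is a receptor plus exactly one posed small-molecule
ligand.  Atom storage uses :class:`biotite.structure.AtomArray`, so PDB
reading/writing, altloc resolution and residue iteration come from biotite;
this module adds the domain operations every downstream analysis needs:

* binding-pocket definition by a distance cutoff from seed atoms,
* partition of a 7-TM receptor into extracellular (flexible) and
  cytoplasmic (static) regions at the Ballesteros-Weinstein anchor row,
* loop trimming that keeps only the transmembrane bundle and the distal
  half of extracellular loop 2 (downstream of its conserved cysteine),
* least-squares (Kabsch) superposition of pockets on their C-alpha atoms.

Residue identifiers are ``"<chain>:<resid>"`` strings (author numbering,
taken verbatim from the PDB file); insertion codes are appended when
present, e.g. ``"A:52A"``.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, replace

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from .errors import (
    AnnotationError,
    CorrespondenceError,
    EmptyPocketError,
    FormatError,
    MappingError,
    SelectorError,
)

__all__ = [
    "Complex",
    "BindingPocket",
    "TopologyAnnotation",
    "RegionPartition",
    "read_complex",
    "write_complex",
    "define_pocket",
    "partition_regions",
    "trim_loops",
    "superimpose_pockets",
    "kabsch_fit",
    "pocket_seed_points",
    "polar_group_centroids",
    "POLAR_RESIDUES",
]

# Residue types whose side chain bears an H-bond-capable or charged group.
POLAR_RESIDUES = frozenset(
    {"SER", "THR", "CYS", "TYR", "ASN", "GLN", "ASP", "GLU",
     "LYS", "ARG", "HIS", "TRP"}
)

# Side-chain atoms constituting the polar group of each polar residue type
# (used for polar-conservation measurements; heavy atoms only).
POLAR_GROUP_ATOMS = {
    "SER": ("OG",),
    "THR": ("OG1",),
    "CYS": ("SG",),
    "TYR": ("OH",),
    "ASN": ("OD1", "ND2"),
    "GLN": ("OE1", "NE2"),
    "ASP": ("OD1", "OD2"),
    "GLU": ("OE1", "OE2"),
    "LYS": ("NZ",),
    "ARG": ("NE", "NH1", "NH2"),
    "HIS": ("ND1", "NE2"),
    "TRP": ("NE1",),
}

_WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}

#: the seven Ballesteros-Weinstein anchor positions separating the flexible
#: extracellular region from the static cytoplasmic region
BW_ANCHORS = ("1.48", "2.51", "3.38", "4.51", "5.50", "6.43", "7.45")


def _res_key(chain: str, res_id: int, ins_code: str = "") -> str:
    return f"{chain}:{res_id}{ins_code.strip()}"


def atom_res_keys(atoms: struc.AtomArray) -> np.ndarray:
    """Per-atom residue identifier strings."""
    ins = atoms.ins_code if "ins_code" in atoms.get_annotation_categories() \
        else np.full(atoms.array_length(), "")
    return np.array(
        [_res_key(c, r, i) for c, r, i in zip(atoms.chain_id, atoms.res_id, ins)]
    )


@dataclass
class Complex:
    """A receptor structure plus one posed ligand.

    Invariants: all coordinates finite; exactly one ligand entity (one
    hetero residue); residue ids unique per chain on the receptor.
    """

    receptor: struc.AtomArray
    ligand: struc.AtomArray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        for arr, name in ((self.receptor, "receptor"), (self.ligand, "ligand")):
            if arr.array_length() and not np.all(np.isfinite(arr.coord)):
                raise FormatError(f"non-finite coordinates in {name}")
        if self.ligand.array_length() == 0:
            raise SelectorError("complex has no ligand atoms")
        lig_entities = set(zip(self.ligand.chain_id, self.ligand.res_id))
        if len(lig_entities) != 1:
            raise SelectorError(
                f"expected exactly one ligand entity, found {len(lig_entities)}"
            )

    # -- convenience accessors -------------------------------------------
    def copy(self) -> "Complex":
        return Complex(self.receptor.copy(), self.ligand.copy(),
                       dict(self.metadata))

    @property
    def residue_keys(self) -> list[str]:
        """Ordered unique residue ids of the receptor (file order)."""
        keys = atom_res_keys(self.receptor)
        seen, out = set(), []
        for k in keys:
            if k not in seen:
                seen.add(k)
                out.append(k)
        return out

    def receptor_mask(self, residue_keys) -> np.ndarray:
        wanted = set(residue_keys)
        return np.array([k in wanted for k in atom_res_keys(self.receptor)])

    def residue_atoms(self, key: str) -> struc.AtomArray:
        return self.receptor[self.receptor_mask([key])]


@dataclass
class BindingPocket:
    """Ordered pocket residues with C-alpha coordinates and polarity flags."""

    residues: tuple[str, ...]
    ca_coords: np.ndarray          # (n, 3) Angstrom
    polar_mask: np.ndarray         # (n,) bool

    def __post_init__(self):
        self.residues = tuple(self.residues)
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.polar_mask = np.asarray(self.polar_mask, dtype=bool)
        if len(self.residues) < 1:
            raise EmptyPocketError("pocket must contain at least one residue")
        if self.ca_coords.shape != (len(self.residues), 3):
            raise FormatError("ca_coords shape does not match residue count")

    def __len__(self):
        return len(self.residues)


@dataclass
class TopologyAnnotation:
    """Per-residue segment labels (TM1-7, ECL/ICL, termini) for one chain.

    ``segments`` maps each label to an inclusive ``(start, end)`` residue
    number range; ``ecl2_cysteine`` is the conserved disulfide cysteine
    inside ECL2, the boundary of the retained ECL2-distal segment.
    """

    segments: dict[str, tuple[int, int]]
    ecl2_cysteine: int
    chain: str = "A"

    def label_of(self, res_id: int) -> str | None:
        for label, (start, end) in self.segments.items():
            if start <= res_id <= end:
                return label
        return None

    @classmethod
    def from_json(cls, text: str) -> "TopologyAnnotation":
        obj = json.loads(text)
        segments = {s["label"]: (int(s["start"]), int(s["end"]))
                    for s in obj["segments"]}
        return cls(segments=segments,
                   ecl2_cysteine=int(obj["ecl2_cysteine"]),
                   chain=obj.get("chain", "A"))

    def to_json(self) -> str:
        return json.dumps(
            {
                "segments": [
                    {"label": lb, "start": s, "end": e}
                    for lb, (s, e) in self.segments.items()
                ],
                "ecl2_cysteine": self.ecl2_cysteine,
                "chain": self.chain,
            },
            indent=2,
        )


@dataclass
class RegionPartition:
    """Disjoint extracellular / cytoplasmic split of the receptor."""

    extracellular_residues: frozenset[str]
    cytoplasmic_residues: frozenset[str]
    anchor_residues: dict[str, str]

    def __post_init__(self):
        overlap = self.extracellular_residues & self.cytoplasmic_residues
        if overlap:
            raise AnnotationError(f"regions overlap on {sorted(overlap)[:5]}")


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------

def _validate_pdb_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM", "HETATM")):
            try:
                float(line[30:38]); float(line[38:46]); float(line[46:54])
            except (ValueError, IndexError):
                raise FormatError(
                    f"unparseable coordinate record at line {lineno}: {line!r}"
                ) from None


def read_complex(pdb_text, ligand_selector: str) -> Complex:
    """Read a PDB file and split it into receptor and one ligand.

    Parameters
    ----------
    pdb_text
        PDB content as a string or text stream (ATOM/HETATM/TER records).
    ligand_selector
        Either a hetero residue name (e.g. ``"LIG"``) or ``"chain:resid"``
        (e.g. ``"A:401"``).  Must match exactly one hetero entity.

    Waters and unselected hetero entities are dropped.  Alternate locations
    are resolved to the highest-occupancy conformer (ties: first in file,
    i.e. alphabetical altloc id).
    """
    if hasattr(pdb_text, "read"):
        pdb_text = pdb_text.read()
    _validate_pdb_lines(pdb_text)
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb.get_structure(
            model=1, altloc="occupancy", extra_fields=["occupancy", "charge"]
        )
    except FormatError:
        raise
    except Exception as exc:  # biotite parse failure
        raise FormatError(f"PDB parse error: {exc}") from exc

    hetero = atoms[atoms.hetero]
    water = np.isin(hetero.res_name, list(_WATER_NAMES))
    hetero = hetero[~water]

    entities = {}
    for chain, res_id, res_name in zip(
        hetero.chain_id, hetero.res_id, hetero.res_name
    ):
        entities.setdefault((str(chain), int(res_id)), str(res_name))

    if ":" in ligand_selector:
        chain, resid = ligand_selector.split(":", 1)
        matches = [k for k in entities if k == (chain, int(resid))]
    else:
        matches = [k for k, name in entities.items() if name == ligand_selector]
    if len(matches) == 0:
        raise SelectorError(
            f"ligand selector {ligand_selector!r} matched no hetero entity "
            f"(available: {sorted(set(entities.values())) or 'none'})"
        )
    if len(matches) > 1:
        raise SelectorError(
            f"ligand selector {ligand_selector!r} matched "
            f"{len(matches)} entities: {sorted(matches)}"
        )
    chain, resid = matches[0]
    lig_mask = (hetero.chain_id == chain) & (hetero.res_id == resid)
    ligand = hetero[lig_mask]
    receptor = atoms[~atoms.hetero]

    # receptor residue ids unique per chain by construction of the grouping;
    # verify monotone grouping (duplicate non-contiguous ids indicate damage)
    keys = atom_res_keys(receptor)
    first_seen, last_pos = {}, {}
    for pos, k in enumerate(keys):
        if k in last_pos and pos != last_pos[k] + 1:
            raise FormatError(f"residue {k} appears in two separate blocks")
        first_seen.setdefault(k, pos)
        last_pos[k] = pos

    return Complex(receptor=receptor, ligand=ligand,
                   metadata={"ligand_selector": ligand_selector})


def write_complex(cpx: Complex) -> str:
    """Serialise a complex to PDB text (receptor ATOM + ligand HETATM)."""
    merged = cpx.receptor + cpx.ligand
    pdb = PDBFile()
    pdb.set_structure(merged)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Pocket definition
# ---------------------------------------------------------------------------

def pocket_seed_points(ligand: struc.AtomArray, padding: float = 2.0) -> np.ndarray:
    """Cavity seed points: ligand heavy atoms plus a shell of offset points.

    The padded shell approximates the envelope of the ligand-occupied
    cavity, so a small residue-selection cutoff (default 1.5 A) captures
    the residues lining the cavity rather than only clashing atoms.
    """
    heavy = ligand[ligand.element != "H"]
    pts = [heavy.coord]
    if padding > 0:
        dirs = np.array(
            [(i, j, k) for i in (-1, 0, 1) for j in (-1, 0, 1)
             for k in (-1, 0, 1) if (i, j, k) != (0, 0, 0)],
            dtype=float,
        )
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for d in dirs:
            pts.append(heavy.coord + padding * d)
    return np.vstack(pts)


def define_pocket(cpx: Complex, seed=None, cutoff: float = 1.5) -> BindingPocket:
    """Select pocket residues within ``cutoff`` (inclusive) of seed points.

    A residue belongs to the pocket when ANY of its heavy atoms lies at
    distance <= cutoff from any seed point.  ``seed`` defaults to the
    padded envelope of the bound ligand (:func:`pocket_seed_points`).
    Residues are ordered by (chain, residue number, insertion code);
    ``polar_mask`` is looked up from a fixed residue-type table.
    """
    if cutoff <= 0:
        raise EmptyPocketError(f"cutoff must be positive, got {cutoff}")
    if seed is None:
        seed = pocket_seed_points(cpx.ligand)
    seed = np.asarray(seed, dtype=float).reshape(-1, 3)
    if seed.shape[0] == 0:
        raise EmptyPocketError("empty seed atom set")

    rec = cpx.receptor
    heavy = rec.element != "H"
    tree = cKDTree(seed)
    dmin = tree.query(rec.coord[heavy])[0]
    hit_keys = set(atom_res_keys(rec[heavy])[dmin <= cutoff])
    if not hit_keys:
        raise EmptyPocketError(
            f"no residue within {cutoff} A of the seed; "
            "check the seed atoms or enlarge the cutoff"
        )

    ins = rec.ins_code if "ins_code" in rec.get_annotation_categories() \
        else np.full(rec.array_length(), "")
    # one entry per residue, sortable key
    order = {}
    for chain, res_id, ic, name, atom in zip(
        rec.chain_id, rec.res_id, ins, rec.res_name, rec.atom_name
    ):
        key = _res_key(chain, res_id, ic)
        if key in hit_keys and key not in order:
            order[key] = (str(chain), int(res_id), str(ic), str(name))
    keys_sorted = sorted(order, key=lambda k: order[k][:3])

    ca, polar = [], []
    keys_all = atom_res_keys(rec)
    for key in keys_sorted:
        res_atoms = rec[keys_all == key]
        ca_sel = res_atoms[res_atoms.atom_name == "CA"]
        if ca_sel.array_length() == 0:
            raise FormatError(f"pocket residue {key} has no CA atom")
        ca.append(ca_sel.coord[0])
        polar.append(order[key][3] in POLAR_RESIDUES)
    return BindingPocket(tuple(keys_sorted), np.array(ca), np.array(polar))


def polar_group_centroids(cpx: Complex, pocket: BindingPocket) -> dict[str, np.ndarray]:
    """Centroid of the polar side-chain group of each polar pocket residue."""
    out = {}
    keys_all = atom_res_keys(cpx.receptor)
    for key, is_polar in zip(pocket.residues, pocket.polar_mask):
        if not is_polar:
            continue
        res_atoms = cpx.receptor[keys_all == key]
        res_name = str(res_atoms.res_name[0])
        names = POLAR_GROUP_ATOMS.get(res_name, ())
        sel = res_atoms[np.isin(res_atoms.atom_name, list(names))]
        if sel.array_length():
            out[key] = sel.coord.mean(axis=0)
    return out


# ---------------------------------------------------------------------------
# Region partition and loop trimming
# ---------------------------------------------------------------------------

def _parse_res_ref(ref: str, default_chain: str = "A") -> tuple[str, int]:
    if ":" in str(ref):
        chain, rid = str(ref).split(":", 1)
        return chain, int(rid)
    return default_chain, int(ref)


def _tm_extracellular_end(label: str, topology: TopologyAnnotation) -> int:
    """Residue number of the extracellular end of a TM helix.

    Inferred from the flanking segments: the end adjacent to an ECL is
    extracellular.  Falls back to the alternating-topology parity rule
    (odd helices run extracellular->cytoplasmic along the sequence).
    """
    start, end = topology.segments[label]
    before = topology.label_of(start - 1)
    after = topology.label_of(end + 1)
    if after is not None and after.startswith("ECL"):
        return end
    if before is not None and before.startswith("ECL"):
        return start
    helix = int(label[2:])
    return start if helix % 2 == 1 else end


def partition_regions(
    cpx: Complex, topology: TopologyAnnotation, bw_map: dict[str, str]
) -> RegionPartition:
    """Split receptor residues into extracellular and cytoplasmic regions.

    For each of TM2-TM7 the residues strictly extracellular of its
    Ballesteros-Weinstein anchor (1.48, 2.51, 3.38, 4.51, 5.50, 6.43,
    7.45) belong to the extracellular (flexible) region; the anchor itself
    and everything below, plus the whole of TM1, are cytoplasmic (static).
    ECL segments present in the complex are extracellular; ICLs and
    termini are cytoplasmic.
    """
    anchors = {}
    for bw in BW_ANCHORS:
        if bw not in bw_map:
            raise MappingError(f"Ballesteros-Weinstein anchor {bw} missing from map")
        chain, rid = _parse_res_ref(bw_map[bw], topology.chain)
        anchors[bw] = (chain, rid)

    present = cpx.residue_keys
    present_ids = {}
    for key in present:
        chain, rid_s = key.split(":", 1)
        present_ids[key] = (chain, int("".join(ch for ch in rid_s if ch not in
                                               "ABCDEFGHIJKLMNOPQRSTUVWXYZ")))
    for bw, (chain, rid) in anchors.items():
        if _res_key(chain, rid) not in present:
            raise MappingError(
                f"anchor {bw} maps to {chain}:{rid}, absent from the complex"
            )

    extracellular, cytoplasmic = set(), set()
    for key, (chain, rid) in present_ids.items():
        label = topology.label_of(rid)
        if label is None:
            raise AnnotationError(f"residue {key} not covered by the topology")
        if label.startswith("ECL"):
            extracellular.add(key)
        elif label.startswith(("ICL", "NTERM", "CTERM", "H8")):
            cytoplasmic.add(key)
        elif label == "TM1":
            cytoplasmic.add(key)
        elif label.startswith("TM"):
            helix = int(label[2:])
            bw = BW_ANCHORS[helix - 1]
            _, anchor_rid = anchors[bw]
            ec_end = _tm_extracellular_end(label, topology)
            if ec_end >= anchor_rid:      # extracellular end at high resid
                side_ec = rid > anchor_rid
            else:                          # extracellular end at low resid
                side_ec = rid < anchor_rid
            (extracellular if side_ec else cytoplasmic).add(key)
        else:
            raise AnnotationError(f"unknown segment label {label!r}")

    return RegionPartition(
        extracellular_residues=frozenset(extracellular),
        cytoplasmic_residues=frozenset(cytoplasmic),
        anchor_residues={bw: _res_key(c, r) for bw, (c, r) in anchors.items()},
    )


def trim_loops(cpx: Complex, topology: TopologyAnnotation) -> Complex:
    """Delete dynamic loops, keeping the TM bundle and ECL2-distal.

    Removes ECL1, ECL3, all ICLs and termini, and the portion of ECL2
    upstream of the conserved cysteine.  The cysteine itself is retained:
    it anchors the disulfide to TM3 and so moves with the bundle, not with
    the deleted proximal loop.  Idempotent.
    """
    keep = []
    for key in cpx.residue_keys:
        chain, rid_s = key.split(":", 1)
        rid = int("".join(ch for ch in rid_s if ch.isdigit() or ch == "-"))
        label = topology.label_of(rid)
        if label is None:
            raise AnnotationError(f"residue {key} not covered by the topology")
        if label.startswith("TM") or label == "H8":
            keep.append(key)
        elif label == "ECL2" and rid >= topology.ecl2_cysteine:
            keep.append(key)
        # ECL1, ECL3, ICLs, termini, ECL2 upstream of the cysteine: dropped
    mask = cpx.receptor_mask(keep)
    return Complex(receptor=cpx.receptor[mask], ligand=cpx.ligand.copy(),
                   metadata=dict(cpx.metadata))


# ---------------------------------------------------------------------------
# Superposition
# ---------------------------------------------------------------------------

def kabsch_fit(ref: np.ndarray, mov: np.ndarray) -> tuple[np.ndarray, float]:
    """Least-squares rigid fit of ``mov`` onto ``ref``.

    Returns the transformed coordinates and the post-fit RMSD.  Uses the
    quaternion/SVD solver from :mod:`scipy.spatial.transform`.
    """
    ref = np.asarray(ref, float)
    mov = np.asarray(mov, float)
    ref_c = ref - ref.mean(axis=0)
    mov_c = mov - mov.mean(axis=0)
    rot, _ = Rotation.align_vectors(ref_c, mov_c)
    fitted = rot.apply(mov_c) + ref.mean(axis=0)
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - ref) ** 2, axis=1))))
    if rmsd < 1e-7:  # numerical noise of the SVD on identical inputs
        rmsd = 0.0
    return fitted, rmsd


def superimpose_pockets(
    reference: BindingPocket, targets: list[BindingPocket]
) -> tuple[list[np.ndarray], np.ndarray]:
    """Superimpose each target pocket onto the reference on C-alpha atoms.

    All pockets must share the identical ordered residue list.  Returns the
    aligned coordinate matrices and the per-target post-fit RMSD (A).  The
    reference is never modified.
    """
    aligned, rmsds = [], []
    for tgt in targets:
        if tgt.residues != reference.residues:
            diff = set(tgt.residues) ^ set(reference.residues)
            raise CorrespondenceError(
                f"pocket residue lists differ; symmetric difference: "
                f"{sorted(diff)}"
            )
        fitted, rmsd = kabsch_fit(reference.ca_coords, tgt.ca_coords)
        aligned.append(fitted)
        rmsds.append(rmsd)
    return aligned, np.array(rmsds)
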