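"""Protein-ligand interaction fingerprints and their Jaccard analysis.

An interaction fingerprint (IFP) encodes, for every binding-pocket
residue, the presence/absence of eight interaction types with the bound
ligand: hydrophobic, H-bond (donor / acceptor), weak H-bond (donor /
acceptor), ionic (positive / negative) and aromatic.  All criteria are
heavy-atom geometric rules with configurable thresholds
(:class:`IFPCriteria`); hydrogens are never required.

Fingerprints are compared with the Jaccard distance

    d_J(u, v) = (C_TF + C_FT) / (C_TT + C_TF + C_FT)

where ``C_ij`` counts positions k with ``u[k] = i`` and ``v[k] = j``.
Identical fingerprints have distance 0; fingerprints with disjoint
support have distance 1.  Sets of fingerprints are clustered
agglomeratively on the pairwise Jaccard matrix and cut at a distance
threshold (default 0.6) to yield IFP clusters, each represented by its
best-scoring member.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import networkx as nx
import biotite.structure as struc
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .core_model import Complex, BindingPocket, atom_res_keys
from .errors import CorrespondenceError, DimensionError, RankingError

__all__ = [
    "INTERACTION_TYPES",
    "IFPCriteria",
    "InteractionFingerprint",
    "JaccardResult",
    "IFPClusterSet",
    "compute_ifp",
    "jaccard_distance",
    "cluster_ifps",
    "select_representatives",
]

INTERACTION_TYPES = (
    "hydrophobic",
    "Hbond_donor",
    "Hbond_acceptor",
    "weakHbond_donor",
    "weakHbond_acceptor",
    "ionic_positive",
    "ionic_negative",
    "aromatic",
)

# ---------------------------------------------------------------------------
# Atom-role tables for the 20 standard residues (heavy atoms only)
# ---------------------------------------------------------------------------

# Apolar side-chain carbons / sulfurs eligible for hydrophobic contacts.
APOLAR_ATOMS = {
    "ALA": {"CB"},
    "VAL": {"CB", "CG1", "CG2"},
    "LEU": {"CB", "CG", "CD1", "CD2"},
    "ILE": {"CB", "CG1", "CG2", "CD1"},
    "MET": {"CB", "CG", "SD", "CE"},
    "PHE": {"CB", "CG", "CD1", "CD2", "CE1", "CE2", "CZ"},
    "TRP": {"CB", "CG", "CD2", "CE3", "CZ2", "CZ3", "CH2"},
    "PRO": {"CB", "CG", "CD"},
    "TYR": {"CB", "CG", "CD1", "CD2", "CE1", "CE2"},
    "ARG": {"CB", "CG", "CD"},
    "LYS": {"CB", "CG", "CD"},
    "GLN": {"CB", "CG"},
    "GLU": {"CB", "CG"},
    "ASP": {"CB"},
    "ASN": {"CB"},
    "THR": {"CG2"},
    "CYS": {"CB", "SG"},
    "HIS": {"CB"},
    "SER": set(),
    "GLY": set(),
}

# Side-chain H-bond donor heavy atoms, with their covalent antecedent when
# one exists (used for the optional donor-angle criterion).
DONOR_ATOMS = {
    "SER": {"OG": "CB"},
    "THR": {"OG1": "CB"},
    "TYR": {"OH": "CZ"},
    "ASN": {"ND2": "CG"},
    "GLN": {"NE2": "CD"},
    "HIS": {"ND1": None, "NE2": None},
    "LYS": {"NZ": "CE"},
    "ARG": {"NE": "CD", "NH1": "CZ", "NH2": "CZ"},
    "TRP": {"NE1": None},
    "CYS": {"SG": "CB"},
}

# Side-chain H-bond acceptor heavy atoms.
ACCEPTOR_ATOMS = {
    "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"},
    "ASN": {"OD1"},
    "GLN": {"OE1"},
    "SER": {"OG"},
    "THR": {"OG1"},
    "TYR": {"OH"},
    "HIS": {"ND1", "NE2"},
}

# Formally charged side-chain groups (no pKa model: fixed assignment).
CHARGED_ATOMS = {
    "ASP": ({"OD1", "OD2"}, -1),
    "GLU": ({"OE1", "OE2"}, -1),
    "LYS": ({"NZ"}, +1),
    "ARG": ({"NE", "NH1", "NH2", "CZ"}, +1),
}

# Aromatic ring atom names per residue type (TRP: fused system as one ring
# set per ring; HIS imidazole included).
AROMATIC_RINGS = {
    "PHE": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TYR": [("CG", "CD1", "CD2", "CE1", "CE2", "CZ")],
    "TRP": [("CG", "CD1", "NE1", "CE2", "CD2"),
            ("CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3")],
    "HIS": [("CG", "ND1", "CD2", "CE1", "NE2")],
}

_BACKBONE_DONOR = "N"
_BACKBONE_ACCEPTOR = "O"


@dataclass
class IFPCriteria:
    """Geometric thresholds for interaction detection (A / degrees)."""

    hydrophobic_max: float = 4.5
    hbond_max: float = 3.5
    hbond_min_angle: float = 120.0   # antecedent-donor-acceptor, when defined
    weak_hbond_max: float = 3.8
    ionic_max: float = 4.0
    aromatic_centroid_max: float = 4.5
    aromatic_face_max_angle: float = 30.0
    aromatic_edge_min_angle: float = 60.0
    include_backbone: bool = True


@dataclass
class InteractionFingerprint:
    """Ordered boolean interaction matrix over pocket residues x 8 types."""

    residues: tuple[str, ...]
    bits: np.ndarray                 # (n_residues, 8) bool
    model_id: str = ""

    def __post_init__(self):
        self.residues = tuple(self.residues)
        self.bits = np.asarray(self.bits, dtype=bool)
        if self.bits.shape != (len(self.residues), len(INTERACTION_TYPES)):
            raise DimensionError(
                f"bits shape {self.bits.shape} does not match "
                f"{len(self.residues)} residues x {len(INTERACTION_TYPES)} types"
            )

    def flatten(self) -> np.ndarray:
        """Residue-major flattened boolean vector (length 8 * n_residues)."""
        return self.bits.reshape(-1)

    def comparable_with(self, other: "InteractionFingerprint") -> bool:
        return self.residues == other.residues


# ---------------------------------------------------------------------------
# Ligand typing
# ---------------------------------------------------------------------------

def _ligand_bond_graph(ligand: struc.AtomArray) -> nx.Graph:
    heavy_idx = np.where(ligand.element != "H")[0]
    g = nx.Graph()
    g.add_nodes_from(heavy_idx.tolist())
    try:
        bonds = struc.connect_via_distances(ligand)
        for i, j, _ in bonds.as_array():
            if ligand.element[i] != "H" and ligand.element[j] != "H":
                g.add_edge(int(i), int(j))
    except Exception:
        # fall back to a plain distance rule
        coord = ligand.coord
        for a in heavy_idx:
            for b in heavy_idx:
                if a < b and np.linalg.norm(coord[a] - coord[b]) < 1.8:
                    g.add_edge(int(a), int(b))
    return g


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centroid and unit normal of a (near-planar) ring."""
    centroid = coords.mean(axis=0)
    centered = coords - centroid
    _, _, vt = np.linalg.svd(centered)
    return centroid, vt[2]


def _ligand_rings(ligand: struc.AtomArray) -> list[np.ndarray]:
    """5/6-membered near-planar carbon-rich rings (index arrays)."""
    g = _ligand_bond_graph(ligand)
    rings = []
    for cycle in nx.cycle_basis(g):
        if len(cycle) not in (5, 6):
            continue
        coords = ligand.coord[np.array(cycle)]
        centroid, normal = _ring_plane(coords)
        planarity = np.abs((coords - centroid) @ normal).max()
        if planarity < 0.35:
            rings.append(np.array(cycle))
    return rings


def _ligand_charges(ligand: struc.AtomArray) -> np.ndarray:
    if "charge" in ligand.get_annotation_categories():
        return np.asarray(ligand.charge, dtype=int)
    return np.zeros(ligand.array_length(), dtype=int)


@dataclass
class _LigandTyping:
    apolar: np.ndarray        # index arrays into the ligand AtomArray
    donors: np.ndarray
    acceptors: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    weak_donors: np.ndarray   # aromatic / alpha carbons
    rings: list[np.ndarray]

    @classmethod
    def from_ligand(cls, ligand: struc.AtomArray) -> "_LigandTyping":
        elem = np.char.upper(ligand.element.astype("U2"))
        charge = _ligand_charges(ligand)
        rings = _ligand_rings(ligand)
        ring_atoms = (
            np.unique(np.concatenate(rings)) if rings else np.array([], int)
        )
        apolar = np.where(np.isin(elem, ["C", "S"]))[0]
        donors = np.where(np.isin(elem, ["N"]) | (charge > 0))[0]
        acceptors = np.where(np.isin(elem, ["O"]) | (charge < 0))[0]
        positive = np.where(charge > 0)[0]
        negative = np.where(charge < 0)[0]
        weak = np.array(
            sorted(set(ring_atoms.tolist())
                   & set(np.where(elem == "C")[0].tolist())),
            dtype=int,
        )
        return cls(apolar, donors, acceptors, positive, negative, weak, rings)


# ---------------------------------------------------------------------------
# Fingerprint computation
# ---------------------------------------------------------------------------

def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) == 0 or len(b) == 0:
        return np.inf
    d = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=-1)
    return float(d.min())


def _angle_deg(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    v1, v2 = a - b, c - b
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def compute_ifp(
    cpx: Complex,
    pocket: BindingPocket,
    criteria: IFPCriteria | None = None,
    model_id: str = "",
) -> InteractionFingerprint:
    """Compute the 8-type interaction fingerprint of a complex.

    Each bit is set iff at least one residue-atom / ligand-atom pair (ring
    pair for the aromatic bit) satisfies the corresponding geometric
    criterion.  The ionic bits are named after the LIGAND's charge sign:
    ``ionic_negative`` means an anionic ligand group contacts a cationic
    residue group, and vice versa.
    """
    crit = criteria or IFPCriteria()
    lig = cpx.ligand
    lt = _LigandTyping.from_ligand(lig)
    lig_xyz = lig.coord
    lig_graph = _ligand_bond_graph(lig)

    keys_all = atom_res_keys(cpx.receptor)
    present = set(keys_all)
    bits = np.zeros((len(pocket), len(INTERACTION_TYPES)), dtype=bool)

    for ri, key in enumerate(pocket.residues):
        if key not in present:
            raise CorrespondenceError(f"pocket residue {key} absent from complex")
        res = cpx.receptor[keys_all == key]
        res_name = str(res.res_name[0])
        names = res.atom_name
        xyz = res.coord

        def coords_of(wanted) -> np.ndarray:
            mask = np.isin(names, list(wanted))
            return xyz[mask]

        # 1. hydrophobic
        apolar = coords_of(APOLAR_ATOMS.get(res_name, set()))
        if _min_dist(apolar, lig_xyz[lt.apolar]) <= crit.hydrophobic_max:
            bits[ri, 0] = True

        # 2. H-bond donated by the residue
        donor_table = dict(DONOR_ATOMS.get(res_name, {}))
        if crit.include_backbone:
            donor_table[_BACKBONE_DONOR] = "CA"
        acc_xyz = lig_xyz[lt.acceptors]
        for dname, antecedent in donor_table.items():
            dsel = xyz[names == dname]
            if dsel.shape[0] == 0 or acc_xyz.shape[0] == 0:
                continue
            dpos = dsel[0]
            ante = xyz[names == antecedent][0] if (
                antecedent and (names == antecedent).any()) else None
            dd = np.linalg.norm(acc_xyz - dpos, axis=1)
            for apos, dist in zip(acc_xyz, dd):
                if dist > crit.hbond_max:
                    continue
                if ante is None or _angle_deg(ante, dpos, apos) >= crit.hbond_min_angle:
                    bits[ri, 1] = True
                    break
            if bits[ri, 1]:
                break

        # 3. H-bond accepted by the residue
        acc_names = set(ACCEPTOR_ATOMS.get(res_name, set()))
        if crit.include_backbone:
            acc_names.add(_BACKBONE_ACCEPTOR)
        res_acc = coords_of(acc_names)
        for di in lt.donors:
            dpos = lig_xyz[di]
            if res_acc.shape[0] == 0:
                break
            dd = np.linalg.norm(res_acc - dpos, axis=1)
            neighbors = [lig_xyz[n] for n in lig_graph.neighbors(int(di))]
            for apos, dist in zip(res_acc, dd):
                if dist > crit.hbond_max:
                    continue
                if not neighbors:
                    bits[ri, 2] = True
                    break
                # require at least one antecedent geometry to be plausible
                if max(_angle_deg(n, dpos, apos) for n in neighbors) \
                        >= crit.hbond_min_angle:
                    bits[ri, 2] = True
                    break
            if bits[ri, 2]:
                break

        # 4. weak H-bond donated by the residue (CA / aromatic C donor)
        weak_names = {"CA"} | {
            n for ring in AROMATIC_RINGS.get(res_name, []) for n in ring
            if n.startswith("C")
        }
        if _min_dist(coords_of(weak_names), acc_xyz) <= crit.weak_hbond_max:
            bits[ri, 3] = True

        # 5. weak H-bond accepted by the residue (ligand aromatic C donor)
        if _min_dist(res_acc, lig_xyz[lt.weak_donors]) <= crit.weak_hbond_max:
            bits[ri, 4] = True

        # 6/7. ionic, bit named after the ligand charge sign
        charged = CHARGED_ATOMS.get(res_name)
        if charged is not None:
            gnames, sign = charged
            gxyz = coords_of(gnames)
            if sign < 0 and _min_dist(gxyz, lig_xyz[lt.positive]) <= crit.ionic_max:
                bits[ri, 5] = True   # cationic ligand group: ionic_positive
            if sign > 0 and _min_dist(gxyz, lig_xyz[lt.negative]) <= crit.ionic_max:
                bits[ri, 6] = True   # anionic ligand group: ionic_negative

        # 8. aromatic (face and edge pooled into one bit)
        for ring_names in AROMATIC_RINGS.get(res_name, []):
            rxyz = coords_of(ring_names)
            if rxyz.shape[0] < len(ring_names):
                continue
            c1, n1 = _ring_plane(rxyz)
            for lring in lt.rings:
                c2, n2 = _ring_plane(lig_xyz[lring])
                if np.linalg.norm(c1 - c2) > crit.aromatic_centroid_max:
                    continue
                ang = np.degrees(np.arccos(np.clip(abs(np.dot(n1, n2)), 0, 1)))
                if ang <= crit.aromatic_face_max_angle or \
                        ang >= crit.aromatic_edge_min_angle:
                    bits[ri, 7] = True
                    break
            if bits[ri, 7]:
                break

    return InteractionFingerprint(pocket.residues, bits, model_id=model_id)


# ---------------------------------------------------------------------------
# Jaccard distance
# ---------------------------------------------------------------------------

@dataclass
class JaccardResult:
    """Jaccard distance with its co-occurrence counts."""

    d_J: float
    C_TT: int
    C_TF: int
    C_FT: int


def jaccard_distance(u, v) -> JaccardResult:
    """Jaccard distance between two boolean vectors.

    ``d_J = (C_TF + C_FT) / (C_TT + C_TF + C_FT)``.  When both vectors are
    all-False the ratio is 0/0 and the distance is defined as 0 (identical
    absence of contacts).
    """
    u = np.asarray(u, dtype=bool).reshape(-1)
    v = np.asarray(v, dtype=bool).reshape(-1)
    if u.shape != v.shape:
        raise DimensionError(f"length mismatch: {u.shape[0]} vs {v.shape[0]}")
    if u.shape[0] < 1:
        raise DimensionError("vectors must be non-empty")
    c_tt = int(np.sum(u & v))
    c_tf = int(np.sum(u & ~v))
    c_ft = int(np.sum(~u & v))
    denom = c_tt + c_tf + c_ft
    d = (c_tf + c_ft) / denom if denom > 0 else 0.0
    return JaccardResult(d_J=float(d), C_TT=c_tt, C_TF=c_tf, C_FT=c_ft)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class IFPClusterSet:
    """Result of agglomerative clustering of fingerprints."""

    model_ids: tuple[str, ...]
    linkage: np.ndarray
    cutoff: float
    clusters: dict[str, int]                  # model id -> cluster label
    representatives: dict[int, str] = field(default_factory=dict)

    def members(self, label: int) -> list[str]:
        return sorted(m for m, lb in self.clusters.items() if lb == label)

    @property
    def n_clusters(self) -> int:
        return len(set(self.clusters.values()))

    def to_newick(self) -> str:
        """Dendrogram as a Newick string with merge-height branch lengths."""
        from skbio.tree import TreeNode

        tree = TreeNode.from_linkage_matrix(self.linkage, list(self.model_ids))
        buf = __import__("io").StringIO()
        tree.write(buf)
        return buf.getvalue().strip()


def pairwise_jaccard_matrix(ifps: list[InteractionFingerprint]) -> np.ndarray:
    n = len(ifps)
    mat = np.zeros((n, n))
    flat = [f.flatten() for f in ifps]
    for i in range(n):
        for j in range(i + 1, n):
            mat[i, j] = mat[j, i] = jaccard_distance(flat[i], flat[j]).d_J
    return mat


def cluster_ifps(
    ifps: list[InteractionFingerprint],
    cutoff: float = 0.6,
    method: str = "average",
) -> IFPClusterSet:
    """Agglomerative clustering of fingerprints on Jaccard distances.

    Flat clusters are cut so that two fingerprints at distance >= cutoff
    belong to different clusters (merges strictly below the cutoff are
    kept).  The default cutoff of 0.6 marks two fingerprints as
    "sufficiently different"; lower it when the cluster count explodes.
    """
    if len(ifps) < 2:
        raise DimensionError("need at least two fingerprints to cluster")
    first = ifps[0]
    for f in ifps[1:]:
        if not f.comparable_with(first):
            raise CorrespondenceError(
                "fingerprints cover different residue lists and are not comparable"
            )
    ids = tuple(f.model_id or f"model_{i}" for i, f in enumerate(ifps))
    if len(set(ids)) != len(ids):
        raise DimensionError("model ids must be unique")
    mat = pairwise_jaccard_matrix(ifps)
    z = hierarchy.linkage(squareform(mat, checks=False), method=method)
    labels = hierarchy.fcluster(
        z, t=np.nextafter(cutoff, -np.inf), criterion="distance"
    )
    return IFPClusterSet(
        model_ids=ids,
        linkage=z,
        cutoff=cutoff,
        clusters={mid: int(lb) for mid, lb in zip(ids, labels)},
    )


def select_representatives(
    clusters: IFPClusterSet, ranking: dict[str, float], higher_better: bool = True
) -> dict[int, str]:
    """Pick the best-scoring member of each cluster.

    Ties are broken deterministically by model id ascending.  The chosen
    representatives are also stored on the cluster set.
    """
    missing = [m for m in clusters.model_ids if m not in ranking]
    if missing:
        raise RankingError(f"no score for models: {missing}")
    reps: dict[int, str] = {}
    for label in sorted(set(clusters.clusters.values())):
        members = clusters.members(label)
        key = (lambda m: (-ranking[m], m)) if higher_better \
            else (lambda m: (ranking[m], m))
        reps[label] = min(members, key=key)
    clusters.representatives = reps
    return reps
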