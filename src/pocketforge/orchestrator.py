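"""Iterative ligand-directed refinement engine.

The engine refines a receptor binding pocket around a single known
ligand through independent *replicas*, each running sequential *rounds*;
within a round, parallel *directories* each apply one sampling chain:

    backbone sampling -> pocket-distance filter -> side-chain sampling
    -> polar-conservation filter -> rebuild & minimise -> dock

The best-docking survivor of the round is extracted, fold-scored, and
seeds the next round; everything else is discarded.  The first round
samples the receptor alone (the ligand joins at the docking step); all
later rounds sample the complex that came out of the previous round.
After all rounds, up to ``n_replicas * n_rounds`` models are ranked by
the combined score: dock and fold scores are each min-max normalised
over the output set (1 = most favorable) and averaged with equal
weights.

Both selection filters keep conformational change incremental: the
pocket C-alpha RMSD filter bounds backbone drift per round, and the
polar-conservation filter requires a fraction of the reference pocket's
polar side-chain groups to stay in place (group centroid within a
tolerance after pocket superposition).

All randomness derives from ``master_seed`` through a per-(replica,
round, directory) hash, so results are independent of execution order
and bit-reproducible.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .backends import RunContext, StageBackends
from .core_model import (
    BindingPocket,
    Complex,
    TopologyAnnotation,
    atom_res_keys,
    define_pocket,
    kabsch_fit,
    partition_regions,
    polar_group_centroids,
    pocket_seed_points,
    trim_loops,
)
from .errors import BackendError, ConfigError, RankingError

__all__ = [
    "LDMConfig",
    "LDMModel",
    "run_ldm",
    "pocket_distance_filter",
    "polar_conservation_filter",
    "combined_rank",
    "top_k",
    "derive_seed",
]


@dataclass(frozen=True)
class LDMConfig:
    """Run configuration for the refinement engine.

    The default capacity (16 replicas x 20 rounds = 320 models) and both
    filter cutoffs are this package's own defaults, chosen for a
    plausible production run; every value is expected to be tuned per
    study.  Tests and examples use much smaller replica/round counts.
    """

    n_replicas: int = 16
    n_rounds: int = 20
    n_directories_per_round: int = 8
    pocket_rmsd_cutoff: float = 1.0          # A
    polar_conservation_fraction: float = 0.8
    polar_tolerance: float = 1.5             # A, group-centroid displacement
    refine_radius: float = 2.0               # A, dock refinement shell
    pocket_cutoff: float = 1.5               # A, pocket residue selection
    pocket_seed_padding: float = 2.0         # A, ligand envelope padding
    master_seed: int = 0
    trim: bool = True

    def __post_init__(self):
        for name in ("n_replicas", "n_rounds", "n_directories_per_round"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in ("pocket_rmsd_cutoff", "refine_radius", "pocket_cutoff"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be > 0")
        if not 0 < self.polar_conservation_fraction <= 1:
            raise ConfigError("polar_conservation_fraction must be in (0, 1]")

    @classmethod
    def from_json(cls, text: str) -> "LDMConfig":
        obj = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(obj) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


@dataclass
class LDMModel:
    """One refinement output complex with its scores and provenance."""

    complex: Complex
    dock_score: float
    fold_score: float
    replica: int
    round: int
    combined_score: float | None = None
    name: str | None = None


def derive_seed(master_seed: int, *parts: int) -> int:
    """Stable 63-bit seed for a (replica, round, directory) coordinate."""
    text = ":".join(str(p) for p in (master_seed, *parts))
    digest = hashlib.sha256(text.encode()).digest()
    return int.from_bytes(digest[:8], "little") >> 1


# ---------------------------------------------------------------------------
# Selection filters
# ---------------------------------------------------------------------------

def _pocket_of(cpx: Complex, residues: tuple[str, ...]) -> BindingPocket:
    """Pocket with a FIXED residue list read off a (moved) complex."""
    keys = atom_res_keys(cpx.receptor)
    ca, polar = [], []
    from .core_model import POLAR_RESIDUES

    for key in residues:
        mask = (keys == key) & (cpx.receptor.atom_name == "CA")
        if not mask.any():
            raise BackendError(f"pocket residue {key} lost its CA atom")
        ca.append(cpx.receptor.coord[mask][0])
        res_mask = keys == key
        polar.append(str(cpx.receptor.res_name[res_mask][0]) in POLAR_RESIDUES)
    return BindingPocket(residues, np.array(ca), np.array(polar))


def pocket_distance_filter(
    candidates: list[Complex],
    reference: Complex,
    cutoff: float,
    pocket_residues: tuple[str, ...],
) -> tuple[list[Complex], list[float]]:
    """Keep candidates whose pocket C-alpha RMSD to the reference is <= cutoff.

    RMSD is computed after least-squares superposition of the pocket
    C-alpha atoms, so global rigid drift does not count against a
    candidate.  Returns the survivors and every candidate's RMSD.
    """
    ref_pocket = _pocket_of(reference, pocket_residues)
    kept, rmsds = [], []
    for cand in candidates:
        pocket = _pocket_of(cand, pocket_residues)
        _, rmsd = kabsch_fit(ref_pocket.ca_coords, pocket.ca_coords)
        rmsds.append(rmsd)
        if rmsd <= cutoff:
            kept.append(cand)
    return kept, rmsds


def polar_conservation_filter(
    candidates: list[Complex],
    reference: Complex,
    fraction: float,
    pocket_residues: tuple[str, ...],
    tolerance: float = 1.5,
) -> tuple[list[Complex], list[float]]:
    """Keep candidates conserving enough reference polar pocket groups.

    A polar residue is conserved when its side-chain polar-group centroid
    stays within ``tolerance`` of the reference position after pocket
    C-alpha superposition.  Candidates with conservation >= ``fraction``
    survive.  A reference without polar pocket residues passes everything
    (with a warning).
    """
    ref_pocket = _pocket_of(reference, pocket_residues)
    ref_groups = polar_group_centroids(reference, ref_pocket)
    if not ref_groups:
        warnings.warn("reference pocket has no polar residues; "
                      "polar-conservation filter passes all candidates")
        return list(candidates), [1.0] * len(candidates)

    kept, fractions = [], []
    for cand in candidates:
        pocket = _pocket_of(cand, pocket_residues)
        # rigid transform aligning the candidate pocket onto the reference
        ref_ca = ref_pocket.ca_coords
        mov_ca = pocket.ca_coords
        from scipy.spatial.transform import Rotation

        rot, _ = Rotation.align_vectors(ref_ca - ref_ca.mean(axis=0),
                                        mov_ca - mov_ca.mean(axis=0))
        groups = polar_group_centroids(cand, pocket)
        n_cons = 0
        for key, ref_pos in ref_groups.items():
            if key not in groups:
                continue
            moved = rot.apply(groups[key] - mov_ca.mean(axis=0)) \
                + ref_ca.mean(axis=0)
            if np.linalg.norm(moved - ref_pos) <= tolerance:
                n_cons += 1
        conservation = n_cons / len(ref_groups)
        fractions.append(conservation)
        if conservation >= fraction:
            kept.append(cand)
    return kept, fractions


# ---------------------------------------------------------------------------
# Ranking
# ---------------------------------------------------------------------------

def _minmax_favorable(values: np.ndarray) -> np.ndarray:
    """Min-max normalise lower-is-better scores to [0, 1], 1 = best.

    A zero-range score carries no information: every model gets 0.5.
    """
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.full(len(values), 0.5)
    return (hi - values) / (hi - lo)


def combined_rank(models: list[LDMModel]) -> list[LDMModel]:
    """Equal-weight normalised dock+fold ranking, best first.

    Each score is min-max normalised over the model set and oriented so 1
    is most favorable; the combined score is their mean.  Ties break by
    (dock_score, replica, round).
    """
    if not models:
        raise RankingError("no models to rank")
    for m in models:
        if m.dock_score is None or m.fold_score is None:
            raise RankingError(
                f"model from replica {m.replica} round {m.round} "
                "is missing a score"
            )
    dock = np.array([m.dock_score for m in models], float)
    fold = np.array([m.fold_score for m in models], float)
    combined = 0.5 * _minmax_favorable(dock) + 0.5 * _minmax_favorable(fold)
    for m, c in zip(models, combined):
        m.combined_score = float(c)
    return sorted(
        models,
        key=lambda m: (-m.combined_score, m.dock_score, m.replica, m.round),
    )


def top_k(models: list[LDMModel], k: int = 25) -> list[LDMModel]:
    """First k ranked models, renamed ``LDM 000`` .. ``LDM {k-1:03d}``."""
    if k > len(models):
        warnings.warn(
            f"requested top {k} but only {len(models)} models available"
        )
    out = models[:k]
    for i, m in enumerate(out):
        m.name = f"LDM {i:03d}"
    return out


# ---------------------------------------------------------------------------
# The engine
# ---------------------------------------------------------------------------

def run_ldm(
    config: LDMConfig,
    start: Complex,
    topology: TopologyAnnotation,
    bw_map: dict[str, str],
    backends: StageBackends,
    provenance: list | None = None,
) -> list[LDMModel]:
    """Run the full replica/round refinement and return ranked models.

    ``provenance``, when given a list, receives one dict per directory
    and per round-extraction event (replica, round, directory, filter
    outcomes, scores) — the audit trail for extraction correctness.
    """
    log = provenance if provenance is not None else []

    prepared = trim_loops(start, topology) if config.trim else start.copy()
    partition = partition_regions(prepared, topology, bw_map)
    seed_pts = pocket_seed_points(prepared.ligand,
                                  padding=config.pocket_seed_padding)
    pocket = define_pocket(prepared, seed=seed_pts, cutoff=config.pocket_cutoff)

    static = partition.cytoplasmic_residues
    keys = atom_res_keys(prepared.receptor)
    ref_static = {
        key: prepared.receptor.coord[keys == key].copy() for key in static
    }
    context = RunContext(
        static_residues=static,
        pocket_residues=pocket.residues,
        refine_radius=config.refine_radius,
        reference_static_coords=ref_static,
    )
    backends.bind(context)

    models: list[LDMModel] = []
    for replica in range(config.n_replicas):
        try:
            current = backends.init_relax(
                prepared, derive_seed(config.master_seed, replica)
            )
        except Exception as exc:
            log.append({"event": "replica_abort", "replica": replica,
                        "error": str(exc)})
            continue
        for rnd in range(config.n_rounds):
            survivors: list[tuple[Complex, float, int]] = []
            for d in range(config.n_directories_per_round):
                seed = derive_seed(config.master_seed, replica, rnd, d)
                record = {"replica": replica, "round": rnd, "directory": d}
                try:
                    cand = backends.backbone_sample(current, seed)
                    kept, rmsds = pocket_distance_filter(
                        [cand], current, config.pocket_rmsd_cutoff,
                        pocket.residues,
                    )
                    record["pocket_rmsd"] = round(rmsds[0], 4)
                    if not kept:
                        record["filtered"] = "pocket_distance"
                        log.append(record)
                        continue
                    cand = backends.sidechain_sample(kept[0], seed + 1)
                    kept, fracs = polar_conservation_filter(
                        [cand], current, config.polar_conservation_fraction,
                        pocket.residues, tolerance=config.polar_tolerance,
                    )
                    record["polar_conservation"] = round(fracs[0], 4)
                    if not kept:
                        record["filtered"] = "polar_conservation"
                        log.append(record)
                        continue
                    cand = backends.rebuild_and_minimize(kept[0])
                    docked, dock_score = backends.dock(cand, seed + 2)
                    record["dock_score"] = round(dock_score, 6)
                    log.append(record)
                    survivors.append((docked, dock_score, d))
                except Exception as exc:  # backend failure: abort replica
                    record["error"] = str(exc)
                    log.append(record)
                    log.append({"event": "replica_abort", "replica": replica,
                                "round": rnd, "error": str(exc)})
                    survivors = None
                    break
            if survivors is None:
                break
            if not survivors:
                log.append({"event": "round_empty", "replica": replica,
                            "round": rnd})
                continue  # next round restarts from the same complex
            best_cpx, best_score, best_dir = min(
                survivors, key=lambda t: (t[1], t[2])
            )
            fold = backends.fold_score(best_cpx)
            log.append({
                "event": "extracted", "replica": replica, "round": rnd,
                "directory": best_dir, "dock_score": round(best_score, 6),
                "fold_score": round(fold, 6),
            })
            models.append(LDMModel(
                complex=best_cpx, dock_score=float(best_score),
                fold_score=float(fold), replica=replica, round=rnd,
            ))
            current = best_cpx

    if not models:
        return []
    return combined_rank(models)
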