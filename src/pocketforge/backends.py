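"""Pluggable refinement-stage backends and the in-repo toy implementations.

The iterative refinement engine (:mod:`pocketforge.orchestrator`) drives
six heavy stages through the :class:`StageBackends` contract: initial
relaxation, backbone sampling, side-chain sampling, rebuild-and-minimise,
ligand docking and fold scoring.  In production these stages would be
served by external physics engines; this package ships deliberately
simple toy backends built on seeded jitter, a soft-sphere potential and a
rigid-body pose search.  They are NOT reimplementations of any external
engine — they exist so the orchestration, filtering and scoring logic is
fully testable, and so that a planted pocket optimum can be recovered end
to end.

Contract invariants every backend must honour:

* each stage is a pure function of its inputs and the integer seed
  (replayable, order-independent);
* ``dock`` moves only the ligand and residues within ``refine_radius``
  of it (the toy dock moves the ligand alone);
* scores are lower-is-better for both ``dock`` and ``fold_score``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol, runtime_checkable

import numpy as np

from .core_model import Complex, BindingPocket, atom_res_keys
from .errors import BackendError

__all__ = ["RunContext", "StageBackends", "ToyBackends"]


@dataclass
class RunContext:
    """What a backend may know about the run: regions and the pocket."""

    static_residues: frozenset[str]
    pocket_residues: tuple[str, ...]
    refine_radius: float = 2.0
    reference_static_coords: dict[str, np.ndarray] = field(default_factory=dict)


@runtime_checkable
class StageBackends(Protocol):
    def bind(self, context: RunContext) -> None: ...

    def init_relax(self, cpx: Complex, seed: int) -> Complex: ...

    def backbone_sample(self, cpx: Complex, seed: int) -> Complex: ...

    def sidechain_sample(self, cpx: Complex, seed: int) -> Complex: ...

    def rebuild_and_minimize(self, cpx: Complex) -> Complex: ...

    def dock(self, cpx: Complex, seed: int) -> tuple[Complex, float]: ...

    def fold_score(self, cpx: Complex) -> float: ...


# ---------------------------------------------------------------------------
# Toy backends
# ---------------------------------------------------------------------------

# role sets for the toy dock score (element + charge based, coarse on purpose)
def _lig_roles(ligand):
    elem = np.char.upper(ligand.element.astype("U2"))
    charge = (np.asarray(ligand.charge, int)
              if "charge" in ligand.get_annotation_categories()
              else np.zeros(ligand.array_length(), int))
    positive = charge > 0
    negative = charge < 0
    neutral_polar = np.isin(elem, ["N", "O"]) & (charge == 0)
    apolar = np.isin(elem, ["C", "S"])
    return positive, negative, neutral_polar, apolar


# protein polar atoms by channel, keyed (res_name, atom_name); charge
# channels mirror the fingerprint typing tables
_PROT_ANION = {("ASP", "OD1"), ("ASP", "OD2"), ("GLU", "OE1"), ("GLU", "OE2")}
_PROT_CATION = {("LYS", "NZ"), ("ARG", "NE"), ("ARG", "NH1"), ("ARG", "NH2")}
_PROT_NEUTRAL = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"), ("CYS", "SG"),
    ("ASN", "OD1"), ("ASN", "ND2"), ("GLN", "OE1"), ("GLN", "NE2"),
    ("HIS", "ND1"), ("HIS", "NE2"), ("TRP", "NE1"),
}


@dataclass
class ToyBackends:
    """Seeded-jitter sampling + soft-sphere/contact scoring stages.

    Parameters control sampling amplitudes (A) and the dock pose search.
    ``backbone_amplitude`` displaces whole flexible residues along smooth
    random modes; ``sidechain_amplitude`` jitters side-chain atoms of
    pocket residues; the dock rigid-body search scores poses by a polar
    contact reward minus a soft-sphere clash penalty.
    """

    backbone_amplitude: float = 0.25
    sidechain_amplitude: float = 0.05
    init_amplitude: float = 0.1
    n_poses: int = 40
    pose_translation: float = 0.5
    clash_distance: float = 2.2
    polar_ideal: float = 3.0
    polar_width: float = 0.8
    apolar_ideal: float = 3.8
    apolar_weight: float = 0.3
    clash_weight: float = 5.0
    minimize_steps: int = 10
    #: optional explicit contact wells [(residue_key, atom_name,
    #: ligand_atom_name, ideal_distance, weight), ...].  When set, the dock
    #: reward is the sum of Gaussian wells at these ideal distances, so the
    #: score optimum sits at a caller-designed pocket geometry (the planted
    #: optimum of the recovery tests).  When None, a generic channel score
    #: (charge-matched polar + apolar contacts) is used.
    contact_wells: list | None = None

    def __post_init__(self):
        self._context: RunContext | None = None

    # -- contract ---------------------------------------------------------
    def bind(self, context: RunContext) -> None:
        self._context = context

    def _ctx(self) -> RunContext:
        if self._context is None:
            raise BackendError("toy backends used before bind(context)")
        return self._context

    def _flexible_mask(self, cpx: Complex) -> np.ndarray:
        static = self._ctx().static_residues
        keys = atom_res_keys(cpx.receptor)
        return ~np.isin(keys, list(static))

    def init_relax(self, cpx: Complex, seed: int) -> Complex:
        return self._jitter_residues(cpx, seed, self.init_amplitude,
                                     only_pocket=False)

    def backbone_sample(self, cpx: Complex, seed: int) -> Complex:
        return self._jitter_residues(cpx, seed, self.backbone_amplitude,
                                     only_pocket=False)

    def sidechain_sample(self, cpx: Complex, seed: int) -> Complex:
        out = cpx.copy()
        rng = np.random.default_rng(seed)
        keys = atom_res_keys(out.receptor)
        flexible = self._flexible_mask(out)
        pocket = set(self._ctx().pocket_residues)
        for key in sorted(pocket):
            mask = (keys == key) & flexible & (out.receptor.atom_name != "CA")
            if mask.any():
                out.receptor.coord[mask] += rng.normal(
                    0.0, self.sidechain_amplitude, size=(int(mask.sum()), 3)
                )
        return out

    def rebuild_and_minimize(self, cpx: Complex) -> Complex:
        """Snap the static region to its reference, relieve clashes."""
        ctx = self._ctx()
        out = cpx.copy()
        keys = atom_res_keys(out.receptor)
        for key, coords in ctx.reference_static_coords.items():
            mask = keys == key
            if mask.any():
                out.receptor.coord[mask] = coords
        # steepest descent on a soft-sphere receptor self-repulsion,
        # moving flexible atoms only; bonded context (same or sequence-
        # adjacent residue) is excluded from the repulsion
        flexible = self._flexible_mask(out)
        coord = out.receptor.coord
        rid = out.receptor.res_id
        chain = out.receptor.chain_id
        same_context = (
            (np.abs(rid[:, None] - rid[None, :]) <= 1)
            & (chain[:, None] == chain[None, :])
        )
        for _ in range(self.minimize_steps):
            diff = coord[:, None, :] - coord[None, :, :]
            dist = np.linalg.norm(diff, axis=-1)
            np.fill_diagonal(dist, np.inf)
            dist[same_context] = np.inf
            close = dist < 2.0
            if not close.any():
                break
            with np.errstate(invalid="ignore"):
                push = np.where(
                    close[..., None],
                    (2.0 - dist)[..., None] * diff / dist[..., None],
                    0.0,
                )
            grad = push.sum(axis=1)
            coord[flexible] += 0.2 * grad[flexible]
        out.receptor.coord = coord
        return out

    def dock(self, cpx: Complex, seed: int) -> tuple[Complex, float]:
        """Rigid-ligand pose search; lower scores are more favorable.

        A seeded random rigid search around the incoming pose is followed
        by a derivative-free polish (Nelder-Mead over the six rigid-body
        degrees of freedom), so the returned score measures the pocket at
        its locally best pose rather than echoing the pose history.  Only
        the ligand moves; every receptor atom is left untouched,
        trivially honouring the refine-radius contract.
        """
        from scipy.optimize import minimize

        rng = np.random.default_rng(seed)
        lig = cpx.ligand
        ref_coord = lig.coord.copy()
        center = ref_coord.mean(axis=0)
        wells = self._well_indices(cpx)

        def transform(params: np.ndarray) -> np.ndarray:
            shift, rotvec = params[:3], params[3:]
            angle = np.linalg.norm(rotvec)
            rel = ref_coord - center
            if angle > 1e-12:
                k = rotvec / angle
                cos, sin = np.cos(angle), np.sin(angle)
                rel = (rel * cos + np.cross(k, rel) * sin
                       + np.outer(rel @ k, k) * (1 - cos))
            return rel + center + shift

        def objective(params: np.ndarray) -> float:
            return self._pose_score(cpx, transform(params), wells)

        best_params = np.zeros(6)
        best_score = objective(best_params)
        if wells is not None:
            # harmonic wells: pose fitting is (nonlinear) least squares,
            # solved to convergence by Levenberg-Marquardt with a couple
            # of seeded restarts
            from scipy.optimize import least_squares

            rec_idx, lig_idx, ideals, weights = wells
            rec_xyz = cpx.receptor.coord[rec_idx]
            sqrt_w = np.sqrt(weights)

            def residuals(params: np.ndarray) -> np.ndarray:
                lc = transform(params)
                d = np.linalg.norm(rec_xyz - lc[lig_idx], axis=1)
                return sqrt_w * (d - ideals)

            starts = [np.zeros(6)]
            for _ in range(2):
                starts.append(np.concatenate([
                    rng.uniform(-self.pose_translation,
                                self.pose_translation, size=3),
                    rng.uniform(-0.35, 0.35, size=3),
                ]))
            for p0 in starts:
                try:
                    res = least_squares(residuals, p0, method="lm",
                                        xtol=1e-10, ftol=1e-10)
                except Exception:
                    continue
                s = objective(res.x)
                if s < best_score:
                    best_params, best_score = res.x, s
        else:
            for _ in range(self.n_poses):
                params = np.concatenate([
                    rng.uniform(-self.pose_translation,
                                self.pose_translation, size=3),
                    rng.uniform(-0.35, 0.35, size=3),
                ])
                s = objective(params)
                if s < best_score:
                    best_params, best_score = params, s
            res = minimize(objective, best_params, method="Nelder-Mead",
                           options={"maxiter": 300, "xatol": 1e-3,
                                    "fatol": 1e-8})
            if res.fun < best_score:
                best_params, best_score = res.x, res.fun
        out = cpx.copy()
        out.ligand.coord = transform(best_params)
        return out, float(best_score)

    def fold_score(self, cpx: Complex) -> float:
        """Backbone regularity: virtual C-alpha bond deviations + clashes."""
        rec = cpx.receptor
        ca = rec[rec.atom_name == "CA"]
        score = 0.0
        for chain in np.unique(ca.chain_id):
            sub = ca[ca.chain_id == chain]
            order = np.argsort(sub.res_id)
            rid = sub.res_id[order]
            xyz = sub.coord[order]
            consecutive = np.diff(rid) == 1
            d = np.linalg.norm(np.diff(xyz, axis=0), axis=1)[consecutive]
            score += float(np.sum((d - 3.8) ** 2))
            dist = np.linalg.norm(xyz[:, None] - xyz[None, :], axis=-1)
            iu = np.triu_indices(len(xyz), k=2)
            clash = np.clip(3.5 - dist[iu], 0, None)
            score += float(np.sum(clash ** 2))
        return score

    # -- internals --------------------------------------------------------
    def _jitter_residues(self, cpx: Complex, seed: int, amplitude: float,
                         only_pocket: bool) -> Complex:
        """Smooth per-residue rigid displacements of the flexible region."""
        out = cpx.copy()
        if amplitude <= 0:
            return out
        rng = np.random.default_rng(seed)
        keys = atom_res_keys(out.receptor)
        flexible = self._flexible_mask(out)
        flex_keys = sorted(set(keys[flexible]))
        if only_pocket:
            flex_keys = [k for k in flex_keys
                         if k in set(self._ctx().pocket_residues)]
        # three low-frequency collective modes over the residue index
        n = len(flex_keys)
        if n == 0:
            return out
        t = np.linspace(0, np.pi, n)
        modes = np.stack([np.sin(t), np.cos(t), np.sin(2 * t)])
        weights = rng.normal(size=(3, 3))  # mode x xyz
        disp = modes.T @ weights           # n x 3 smooth field
        disp += rng.normal(0.0, 0.5, size=disp.shape)
        norms = np.linalg.norm(disp, axis=1, keepdims=True)
        disp = disp / np.maximum(norms, 1e-9) \
            * amplitude * rng.uniform(0.3, 1.0, size=(n, 1))
        for key, v in zip(flex_keys, disp):
            out.receptor.coord[keys == key] += v
        return out

    def _well_indices(self, cpx: Complex):
        """Resolve contact wells to atom indices for one complex."""
        if self.contact_wells is None:
            return None
        keys = atom_res_keys(cpx.receptor)
        rec_names = cpx.receptor.atom_name
        lig_names = list(cpx.ligand.atom_name)
        rec_idx, lig_idx, ideals, weights = [], [], [], []
        for res_key, atom_name, lig_atom, ideal, weight in self.contact_wells:
            i = np.flatnonzero((keys == res_key) & (rec_names == atom_name))
            if i.size == 0:
                raise BackendError(
                    f"contact well references missing atom {res_key}:{atom_name}"
                )
            try:
                j = lig_names.index(lig_atom)
            except ValueError:
                raise BackendError(
                    f"contact well references missing ligand atom {lig_atom}"
                ) from None
            rec_idx.append(int(i[0]))
            lig_idx.append(j)
            ideals.append(ideal)
            weights.append(weight)
        return (np.array(rec_idx), np.array(lig_idx),
                np.array(ideals, float), np.array(weights, float))

    def _pose_score(self, cpx: Complex, lig_coord: np.ndarray,
                    wells=None) -> float:
        ctx = self._ctx()
        rec = cpx.receptor
        keys = atom_res_keys(rec)
        pocket_mask = np.isin(keys, list(ctx.pocket_residues))
        rec_xyz = rec.coord
        lig = cpx.ligand
        lig_pos, lig_neg, lig_neu, lig_apolar = _lig_roles(lig)

        d_all = np.linalg.norm(
            rec_xyz[:, None, :] - lig_coord[None, :, :], axis=-1
        )
        clash = np.clip(self.clash_distance - d_all, 0, None)
        penalty = self.clash_weight * float(np.sum(clash ** 2))

        if wells is None:
            wells = self._well_indices(cpx)
        if wells is not None:
            # harmonic restraint network: zero at the designed geometry,
            # growing quadratically with any well-distance violation (no
            # saturation a pose search could exploit)
            rec_idx, lig_idx, ideals, weights = wells
            d = d_all[rec_idx, lig_idx]
            return penalty + float(np.sum(weights * (d - ideals) ** 2))

        # Gaussian contact wells per charge/polarity channel, capped at one
        # ideal contact per protein atom (max over matched ligand partners):
        # the reward is maximised by geometric complementarity of the
        # designed pairing, not by crowding or partner swapping
        res_atom = list(zip(rec.res_name, rec.atom_name))
        sigma = self.polar_width
        reward = 0.0
        channels = (
            (_PROT_ANION, lig_pos, self.polar_ideal, 1.0),
            (_PROT_CATION, lig_neg, self.polar_ideal, 1.0),
            (_PROT_NEUTRAL, lig_neu, self.polar_ideal, 1.0),
        )
        for table, lig_mask, ideal, weight in channels:
            prot_mask = np.array(
                [pair in table for pair in res_atom]
            ) & pocket_mask
            d = d_all[prot_mask][:, lig_mask]
            if d.size:
                per_atom = np.exp(
                    -((d - ideal) ** 2) / (2 * sigma ** 2)
                ).max(axis=1)
                reward += weight * float(per_atom.sum())
        prot_apolar = (
            pocket_mask
            & np.char.startswith(rec.atom_name.astype("U4"), "C")
            & (rec.atom_name != "CA")
        )
        d_ap = d_all[prot_apolar][:, lig_apolar]
        if d_ap.size:
            per_atom = np.exp(
                -((d_ap - self.apolar_ideal) ** 2) / (2 * sigma ** 2)
            ).max(axis=1)
            reward += self.apolar_weight * float(per_atom.sum())
        return penalty - reward
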