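"""Virtual-screening performance metrics.

Implements the retrospective-screening evaluation stack for a ranked
compound library: best-of-repeats docking-score aggregation, ROC curves
for recovery (actives vs decoys) and selectivity (one pharmacology class
vs the other), the normalised square-root AUC

    NSQ_AUC = 100 * (A_sq - 1/3) / (1 - 1/3),
    A_sq    = trapezoidal area of TPR against sqrt(FPR),

which scores 0 for a random ranking, 100 for a perfect one and -50 for a
fully reversed one, enrichment factors at fixed library fractions per
chemotype cluster, pharmacophore-based chemotype clustering, and racemic
library preparation (duplicate removal + enumeration of unassigned
stereocenters).

Scores follow the docking-energy convention: lower is more favorable.
Pass ``higher_better=True`` where the opposite holds.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .errors import ClassError, DataError, DimensionError, IdError, MoleculeError

__all__ = [
    "ScreenTable",
    "ROCCurve",
    "EnrichmentReport",
    "best_of_repeats",
    "ranked_ids",
    "roc_recovery",
    "roc_selectivity",
    "roc_auc",
    "nsq_auc",
    "enrichment_factors",
    "refinement_ligand_rank",
    "cluster_chemotypes",
    "prepare_racemic_library",
]

_ROLES = {"active", "decoy"}
_PHARMACOLOGIES = {"agonist", "inhibitor", "none"}


@dataclass
class ScreenTable:
    """Per-compound screening records.

    ``df`` columns: ``id``, ``role`` (active/decoy), ``pharmacology``
    (agonist/inhibitor/none), ``chemotype`` (label or empty), one or more
    ``score_<k>`` columns, and ``best_score`` once aggregated.
    """

    df: pd.DataFrame
    higher_better: bool = False

    def __post_init__(self):
        df = self.df
        required = {"id", "role", "pharmacology"}
        missing = required - set(df.columns)
        if missing:
            raise DataError(f"screen table missing columns: {sorted(missing)}")
        if df["id"].duplicated().any():
            dups = df.loc[df["id"].duplicated(), "id"].tolist()
            raise DataError(f"duplicate compound ids: {dups[:5]}")
        bad_role = set(df["role"]) - _ROLES
        if bad_role:
            raise DataError(f"unknown roles: {sorted(bad_role)}")
        bad_ph = set(df["pharmacology"]) - _PHARMACOLOGIES
        if bad_ph:
            raise DataError(f"unknown pharmacologies: {sorted(bad_ph)}")
        actives = df[df["role"] == "active"]
        if (actives["pharmacology"] == "none").any():
            bad = actives.loc[actives["pharmacology"] == "none", "id"].tolist()
            raise DataError(f"actives without a pharmacology: {bad[:5]}")
        if not self.score_columns and "best_score" not in df.columns:
            raise DataError("screen table has no score columns")

    @property
    def score_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("score_")]

    def __len__(self):
        return len(self.df)

    @classmethod
    def from_csv(cls, path_or_buf, higher_better: bool = False) -> "ScreenTable":
        df = pd.read_csv(path_or_buf, dtype={"id": str})
        if "chemotype" in df.columns:
            df["chemotype"] = df["chemotype"].fillna("")
        return cls(df, higher_better=higher_better)

    def to_csv(self, path_or_buf) -> None:
        self.df.to_csv(path_or_buf, index=False)


def best_of_repeats(table: ScreenTable) -> ScreenTable:
    """Attribute to each compound the most favorable of its repeat scores."""
    cols = table.score_columns
    if not cols:
        raise DataError("no repeat score columns to aggregate")
    scores = table.df[cols]
    if scores.isna().all(axis=1).any():
        bad = table.df.loc[scores.isna().all(axis=1), "id"].tolist()
        raise DataError(f"compounds with no scores: {bad[:5]}")
    best = scores.max(axis=1) if table.higher_better else scores.min(axis=1)
    df = table.df.copy()
    df["best_score"] = best
    return ScreenTable(df, higher_better=table.higher_better)


def _ensure_best(table: ScreenTable) -> ScreenTable:
    return table if "best_score" in table.df.columns else best_of_repeats(table)


def ranked_ids(table: ScreenTable) -> pd.DataFrame:
    """Ranked copy of the table: favorable scores first, ties by id."""
    table = _ensure_best(table)
    df = table.df.copy()
    key = -df["best_score"] if table.higher_better else df["best_score"]
    df["_key"] = key
    df = df.sort_values(["_key", "id"], kind="stable").drop(columns="_key")
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass
class ROCCurve:
    """Stepwise ROC curve from (0,0) to (1,1) over a strict ranking."""

    fpr: np.ndarray
    tpr: np.ndarray
    ranked: tuple[str, ...]
    positive_label: str
    negative_label: str

    def __post_init__(self):
        self.fpr = np.asarray(self.fpr, float)
        self.tpr = np.asarray(self.tpr, float)
        if np.any(np.diff(self.fpr) < 0) or np.any(np.diff(self.tpr) < 0):
            raise DimensionError("ROC coordinates must be non-decreasing")
        if not (self.fpr[0] == 0 and self.tpr[0] == 0
                and self.fpr[-1] == 1 and self.tpr[-1] == 1):
            raise DimensionError("ROC endpoints must be (0,0) and (1,1)")


def _roc_from_labels(is_pos: np.ndarray, ids, pos_label, neg_label) -> ROCCurve:
    n_pos = int(is_pos.sum())
    n_neg = int(len(is_pos) - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ClassError(
            f"ROC needs both classes; got {n_pos} {pos_label} and "
            f"{n_neg} {neg_label}"
        )
    tpr = np.concatenate([[0.0], np.cumsum(is_pos) / n_pos])
    fpr = np.concatenate([[0.0], np.cumsum(~is_pos) / n_neg])
    return ROCCurve(fpr, tpr, tuple(ids), pos_label, neg_label)


def roc_recovery(table: ScreenTable) -> ROCCurve:
    """ROC for the recovery of actives against decoys."""
    df = ranked_ids(table)
    return _roc_from_labels(
        (df["role"] == "active").to_numpy(), df["id"], "active", "decoy"
    )


def roc_selectivity(table: ScreenTable, positive: str = "agonist") -> ROCCurve:
    """ROC for one pharmacology class against the other; decoys excluded."""
    if positive not in ("agonist", "inhibitor"):
        raise ClassError(f"positive class must be agonist or inhibitor, "
                         f"got {positive!r}")
    negative = "inhibitor" if positive == "agonist" else "agonist"
    df = ranked_ids(table)
    df = df[df["role"] == "active"].reset_index(drop=True)
    for cls in (positive, negative):
        if not (df["pharmacology"] == cls).any():
            raise ClassError(f"no {cls} compounds in the table; "
                             "selectivity is undefined (N/A)")
    return _roc_from_labels(
        (df["pharmacology"] == positive).to_numpy(), df["id"],
        positive, negative,
    )


def roc_auc(roc: ROCCurve) -> float:
    """Ordinary trapezoidal ROC AUC."""
    return float(np.trapezoid(roc.tpr, roc.fpr))


def nsq_auc(roc: ROCCurve) -> float:
    """Normalised square-root AUC of a ROC curve.

    The trapezoidal area of TPR against sqrt(FPR) is rescaled so that the
    random diagonal scores 0 and a perfect classifier scores 100; the
    worst possible ranking scores -50 in the continuous limit.  The
    square-root abscissa emphasises early recovery.
    """
    a_sq = float(np.trapezoid(roc.tpr, np.sqrt(roc.fpr)))
    return 100.0 * (a_sq - 1.0 / 3.0) / (1.0 - 1.0 / 3.0)


# ---------------------------------------------------------------------------
# Enrichment factors
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    """EF per chemotype cluster and library fraction."""

    table: pd.DataFrame  # columns: chemotype, fraction, ef, n_recovered,
    #                               n_cluster, n_top, defined

    def ef(self, chemotype: str, fraction: float) -> float:
        row = self.table[
            (self.table["chemotype"] == chemotype)
            & np.isclose(self.table["fraction"], fraction)
        ]
        if row.empty:
            raise IdError(f"no EF entry for {chemotype!r} at {fraction}")
        return float(row["ef"].iloc[0])


def enrichment_factors(
    table: ScreenTable,
    fractions=(0.01, 0.05, 0.10),
    chemotypes=None,
) -> EnrichmentReport:
    """Enrichment factor of each chemotype cluster at given fractions.

    ``EF = (n_recovered / n_top) / (n_cluster / N)`` with
    ``n_top = ceil(f * N)``, so EF is bounded by ``1/f`` and equals 1 for
    the union of all compounds.  Empty clusters are reported with
    ``defined=False`` rather than raising.
    """
    df = ranked_ids(table)
    n_total = len(df)
    if chemotypes is None:
        chemotypes = sorted(
            {c for c in df.get("chemotype", pd.Series(dtype=str)).fillna("")
             if c}
        )
    rows = []
    for f in fractions:
        if not 0 < f <= 1:
            raise DataError(f"fraction must be in (0, 1], got {f}")
        n_top = math.ceil(f * n_total)
        top = df.iloc[:n_top]
        for cl in chemotypes:
            members = df["chemotype"].fillna("") == cl
            n_cluster = int(members.sum())
            n_rec = int((top["chemotype"].fillna("") == cl).sum())
            if n_cluster == 0:
                rows.append((cl, f, np.nan, 0, 0, n_top, False))
                continue
            ef = (n_rec / n_top) / (n_cluster / n_total)
            rows.append((cl, f, ef, n_rec, n_cluster, n_top, True))
    return EnrichmentReport(
        pd.DataFrame(
            rows,
            columns=["chemotype", "fraction", "ef", "n_recovered",
                     "n_cluster", "n_top", "defined"],
        )
    )


def refinement_ligand_rank(table: ScreenTable, ligand_id: str) -> tuple[int, float]:
    """1-based rank and rank/N percentile of the refinement ligand."""
    df = ranked_ids(table)
    pos = np.flatnonzero((df["id"] == ligand_id).to_numpy())
    if pos.size == 0:
        raise IdError(f"compound {ligand_id!r} not in the table")
    rank = int(pos[0]) + 1
    return rank, rank / len(df)


# ---------------------------------------------------------------------------
# Chemotype clustering (pharmacophore point pairs)
# ---------------------------------------------------------------------------

def _pharmacophore_fp(mol, mol_id: str):
    from rdkit.Chem.Pharm2D import Generate, Gobbi_Pharm2D

    if mol is None:
        raise MoleculeError(f"molecule {mol_id!r} could not be parsed")
    try:
        return Generate.Gen2DFingerprint(mol, Gobbi_Pharm2D.factory)
    except Exception as exc:
        raise MoleculeError(
            f"molecule {mol_id!r} could not be fingerprinted: {exc}"
        ) from exc


def cluster_chemotypes(
    molecules: dict[str, "object"],
    cutoff: float = 0.5,
    method: str = "complete",
) -> dict[str, int]:
    """Cluster molecules into chemotypes on 2D pharmacophore fingerprints.

    ``molecules`` maps compound id to an RDKit Mol.  Distances are
    1 - Tanimoto over pharmacophore point-pair bits; complete-linkage
    agglomeration is cut so molecules at distance >= cutoff separate.
    Labels are stable under input order (ids processed in sorted order,
    clusters numbered by their smallest member id).
    """
    from rdkit import DataStructs

    ids = sorted(molecules)
    if not ids:
        return {}
    fps = [_pharmacophore_fp(molecules[i], i) for i in ids]
    n = len(ids)
    if n == 1:
        return {ids[0]: 1}
    dist = np.zeros((n, n))
    for i in range(n):
        sims = DataStructs.BulkTanimotoSimilarity(fps[i], fps[i + 1:])
        for k, s in enumerate(sims):
            j = i + 1 + k
            dist[i, j] = dist[j, i] = 1.0 - s
    z = hierarchy.linkage(squareform(dist, checks=False), method=method)
    raw = hierarchy.fcluster(z, t=np.nextafter(cutoff, -np.inf),
                             criterion="distance")
    # canonical numbering: cluster of the alphabetically first member is 1
    order: dict[int, int] = {}
    labels: dict[str, int] = {}
    for mol_id, lb in zip(ids, raw):
        if lb not in order:
            order[lb] = len(order) + 1
        labels[mol_id] = order[lb]
    return labels


# ---------------------------------------------------------------------------
# Racemic library preparation
# ---------------------------------------------------------------------------

def prepare_racemic_library(
    molecules: dict[str, "object"], max_isomers: int = 32
) -> tuple[dict[str, "object"], list[str]]:
    """Deduplicate a library and enumerate unassigned stereocenters.

    Exact duplicates (same canonical isomeric SMILES) collapse to the
    first id in sorted order.  Each remaining molecule has its UNASSIGNED
    stereocenters expanded into explicit stereoisomers (ids suffixed
    ``_s0``, ``_s1``, ...); molecules whose enumeration would exceed
    ``max_isomers`` (default 2**5) pass through unexpanded and are listed
    in the returned warnings.  Assigned centers are never touched and no
    tautomers are generated.
    """
    from rdkit import Chem
    from rdkit.Chem.EnumerateStereoisomers import (
        EnumerateStereoisomers,
        GetStereoisomerCount,
        StereoEnumerationOptions,
    )

    seen: dict[str, str] = {}
    unique: dict[str, "object"] = {}
    for mol_id in sorted(molecules):
        mol = molecules[mol_id]
        if mol is None:
            raise MoleculeError(f"molecule {mol_id!r} could not be parsed")
        smi = Chem.MolToSmiles(mol)
        if smi in seen:
            continue
        seen[smi] = mol_id
        unique[mol_id] = mol

    out: dict[str, "object"] = {}
    warnings_list: list[str] = []
    opts = StereoEnumerationOptions(onlyUnassigned=True, unique=True,
                                    maxIsomers=max_isomers)
    for mol_id, mol in unique.items():
        n_iso = GetStereoisomerCount(
            mol, options=StereoEnumerationOptions(onlyUnassigned=True)
        )
        if n_iso > max_isomers:
            warnings_list.append(
                f"{mol_id}: {n_iso} stereoisomers exceed the cap of "
                f"{max_isomers}; passed through unexpanded"
            )
            warnings.warn(warnings_list[-1])
            out[mol_id] = mol
            continue
        isomers = list(EnumerateStereoisomers(mol, options=opts))
        if len(isomers) <= 1:
            out[mol_id] = mol
        else:
            for k, iso in enumerate(isomers):
                out[f"{mol_id}_s{k}"] = iso
    return out, warnings_list
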