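"""Rigid superposition of predicted protein models with outlier pruning.

Calpha coordinate sets are paired (by table or sequence alignment), fitted
with the Kabsch least-squares rotation (reflections excluded), and
iteratively re-fitted after pruning pairs whose post-fit distance exceeds a
cutoff, reporting the final RMSD together with retained/pruned pair counts.
Per-residue confidence is read from the B-factor column of PDB-format model
files; a global model confidence can be supplied alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .marker_screen import verify_motif

#: Reported floor for acceptable global model confidence.
GLOBAL_CONFIDENCE_FLOOR = 0.73

DEFAULT_PRUNE_CUTOFF = 2.0
DEFAULT_MAX_ITER = 100

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class StructureModel:
    """Calpha trace of one model with per-residue confidence."""

    model_id: str
    residue_ids: np.ndarray  # strictly increasing residue numbers
    residue_codes: str  # one-letter codes, same length
    coords: np.ndarray  # (n, 3) Calpha coordinates in Angstrom
    plddt: np.ndarray  # per-residue confidence, 0-100
    global_confidence: Optional[float] = None  # e.g. pTM, 0-1

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.coords = np.asarray(self.coords, dtype=float)
        self.plddt = np.asarray(self.plddt, dtype=float)
        n = len(self.residue_ids)
        if not (len(self.residue_codes) == n == len(self.coords) == len(self.plddt)):
            raise ValueError(f"{self.model_id}: inconsistent residue arrays")
        if n and np.any(np.diff(self.residue_ids) <= 0):
            raise ValueError(f"{self.model_id}: residue indices not strictly increasing")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"{self.model_id}: non-finite coordinates")

    @property
    def sequence(self) -> str:
        return self.residue_codes

    @classmethod
    def from_pdb(
        cls,
        path: str | Path,
        model_id: Optional[str] = None,
        global_confidence: Optional[float] = None,
    ) -> "StructureModel":
        """Read Calpha records from a PDB or mmCIF file.

        Per-residue confidence is taken from the temperature-factor column,
        following the structure-prediction convention of storing pLDDT there.
        """
        from Bio.PDB import MMCIFParser, PDBParser

        path = Path(path)
        parser = (
            MMCIFParser(QUIET=True)
            if path.suffix.lower() in (".cif", ".mmcif")
            else PDBParser(QUIET=True)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            structure = parser.get_structure(model_id or path.stem, str(path))
        resids, codes, coords, plddt = [], [], [], []
        model = next(iter(structure))
        for chain in model:
            for residue in chain:
                if "CA" not in residue:
                    continue
                ca = residue["CA"]
                resids.append(residue.id[1])
                codes.append(_THREE_TO_ONE.get(residue.get_resname(), "X"))
                coords.append(ca.coord)
                plddt.append(ca.get_bfactor())
            break  # first chain only
        return cls(
            model_id=model_id or path.stem,
            residue_ids=np.array(resids),
            residue_codes="".join(codes),
            coords=np.array(coords, dtype=float),
            plddt=np.array(plddt, dtype=float),
            global_confidence=global_confidence,
        )

    def to_pdb(self, path: str | Path) -> None:
        """Write a minimal single-chain Calpha-only PDB file."""
        with open(path, "w") as fh:
            for i in range(len(self.residue_ids)):
                x, y, z = self.coords[i]
                res3 = _ONE_TO_THREE.get(self.residue_codes[i], "UNK")
                fh.write(
                    f"ATOM  {i + 1:5d}  CA  {res3} A{int(self.residue_ids[i]):4d}"
                    f"    {x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{self.plddt[i]:6.2f}"
                    f"           C\n"
                )
            fh.write("END\n")


@dataclass
class SuperpositionResult:
    rotation: np.ndarray  # (3, 3) proper rotation, det +1
    translation: np.ndarray  # (3,)
    rmsd: float
    retained_pairs: int
    pruned_pairs: int
    iterations: int

    def __post_init__(self) -> None:
        if self.rmsd < 0:
            raise ValueError("negative rmsd")
        if self.retained_pairs < 3:
            raise ValueError("fewer than 3 retained pairs")
        R = np.asarray(self.rotation)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8):
            raise ValueError("rotation not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-8):
            raise ValueError("rotation has determinant != +1 (reflection)")


def pair_residues(
    model: StructureModel,
    reference: StructureModel,
    pairing: Optional[Sequence[tuple[int, int]]] = None,
    alignment: Optional[tuple[str, str]] = None,
) -> list[tuple[int, int]]:
    """One-to-one Calpha pairs between model and reference.

    ``pairing`` gives (model_residue_id, reference_residue_id) rows;
    ``alignment`` gives two gapped sequences (model first) whose ungapped
    characters must equal the structures' sequences — gap columns are
    excluded.  Returns ordinal index pairs ordered by model residue index.
    """
    if (pairing is None) == (alignment is None):
        raise ValueError("supply exactly one of pairing or alignment")
    pairs: list[tuple[int, int]] = []
    if pairing is not None:
        m_index = {int(r): i for i, r in enumerate(model.residue_ids)}
        r_index = {int(r): i for i, r in enumerate(reference.residue_ids)}
        seen_m, seen_r = set(), set()
        for mr, rr in pairing:
            if mr in seen_m or rr in seen_r:
                raise ValueError("pairing is not one-to-one")
            seen_m.add(mr)
            seen_r.add(rr)
            if mr not in m_index:
                raise ValueError(f"model residue {mr} not in structure")
            if rr not in r_index:
                raise ValueError(f"reference residue {rr} not in structure")
            pairs.append((m_index[mr], r_index[rr]))
        pairs.sort()
    else:
        a_model, a_ref = alignment
        if len(a_model) != len(a_ref):
            raise ValueError("aligned sequences differ in length")
        if a_model.replace("-", "") != model.sequence:
            raise ValueError("model alignment row does not match model sequence")
        if a_ref.replace("-", "") != reference.sequence:
            raise ValueError("reference alignment row does not match reference sequence")
        i = j = 0
        for cm, cr in zip(a_model, a_ref):
            if cm != "-" and cr != "-":
                pairs.append((i, j))
            if cm != "-":
                i += 1
            if cr != "-":
                j += 1
    if len(pairs) < 3:
        raise ValueError(f"only {len(pairs)} residue pairs (need >= 3)")
    return pairs


def _check_nondegenerate(X: np.ndarray, label: str) -> None:
    c = X - X.mean(axis=0)
    s = np.linalg.svd(c, compute_uv=False)
    if len(s) < 2 or s[1] <= 1e-8 * max(1.0, s[0]):
        raise ValueError(f"{label} point set is collinear or degenerate")


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> SuperpositionResult:
    """Least-squares rigid fit of point set P onto Q (no pruning).

    Returns the proper rotation R and translation t minimising
    ||R p + t - q|| over all pairs, with rmsd the root mean squared residual
    after the fit.  Reflections are excluded; collinear or degenerate inputs
    are rejected.
    """
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("P and Q must be matching (n, 3) arrays")
    if len(P) < 3:
        raise ValueError("need at least 3 pairs")
    _check_nondegenerate(P, "model")
    _check_nondegenerate(Q, "reference")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, _s, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = qc - R @ pc
    resid = (P @ R.T + t) - Q
    rmsd = float(np.sqrt(np.mean(np.sum(resid * resid, axis=1))))
    return SuperpositionResult(
        rotation=R, translation=t, rmsd=rmsd,
        retained_pairs=len(P), pruned_pairs=0, iterations=1,
    )


def prune_and_superpose(
    P: np.ndarray,
    Q: np.ndarray,
    cutoff: float = DEFAULT_PRUNE_CUTOFF,
    max_iter: int = DEFAULT_MAX_ITER,
) -> SuperpositionResult:
    """Iterative fit-prune-refit superposition.

    Each round fits the retained pairs and drops every pair whose post-fit
    distance exceeds ``cutoff`` (Angstrom), until no pair exceeds it,
    ``max_iter`` rounds have run, or a drop would leave fewer than 3 pairs
    (the drop is then not applied).  The reported RMSD is over the final
    retained set and never exceeds the unpruned RMSD.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if len(P) < 3:
        raise ValueError("need at least 3 pairs")
    keep = np.ones(len(P), dtype=bool)
    result = kabsch_superpose(P, Q)
    iterations = 1
    while iterations <= max_iter:
        fitted = P[keep] @ result.rotation.T + result.translation
        dist = np.sqrt(np.sum((fitted - Q[keep]) ** 2, axis=1))
        over = dist > cutoff
        if not over.any():
            break
        if keep.sum() - over.sum() < 3:
            break  # stop before the offending drop
        idx = np.flatnonzero(keep)
        keep[idx[over]] = False
        result = kabsch_superpose(P[keep], Q[keep])
        iterations += 1
    return SuperpositionResult(
        rotation=result.rotation,
        translation=result.translation,
        rmsd=result.rmsd,
        retained_pairs=int(keep.sum()),
        pruned_pairs=int(len(P) - keep.sum()),
        iterations=iterations,
    )


def locate_cap_helix(
    model: StructureModel, aa_sequence: str
) -> Optional[tuple[int, int]]:
    """Residue-id span of the cap-helix motif within a structure.

    ``aa_sequence`` must equal the model's residue codes (consistency
    check); returns (start_residue_id, end_residue_id) of the 8-residue
    motif, or None when the motif is absent.
    """
    if aa_sequence != model.sequence:
        raise ValueError(
            f"{model.model_id}: supplied sequence does not match structure residues"
        )
    start = verify_motif(aa_sequence)
    if start is None:
        return None
    i = start - 1
    return int(model.residue_ids[i]), int(model.residue_ids[i + 7])


def confidence_summary(
    model: StructureModel,
    region: Optional[tuple[int, int]] = None,
) -> dict:
    """Mean per-residue confidence, optionally within a residue-id region.

    Flags the model when its global confidence falls below the reported
    floor of 0.73.
    """
    out = {
        "model_id": model.model_id,
        "mean_plddt": float(np.mean(model.plddt)) if len(model.plddt) else float("nan"),
        "global_confidence": model.global_confidence,
        "low_global_confidence": (
            model.global_confidence is not None
            and model.global_confidence < GLOBAL_CONFIDENCE_FLOOR
        ),
    }
    if region is not None:
        lo, hi = region
        mask = (model.residue_ids >= lo) & (model.residue_ids <= hi)
        out["region"] = (int(lo), int(hi))
        out["region_mean_plddt"] = (
            float(np.mean(model.plddt[mask])) if mask.any() else float("nan")
        )
    return out
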