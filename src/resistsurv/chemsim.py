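"""Insecticide-phytochemical chemical similarity.

Turns SMILES strings into fixed-length binary molecular fingerprints,
computes Tanimoto similarities between them, and builds the per-interaction
diet similarity index: for a pest species and an insecticide, the maximum
Tanimoto similarity between the insecticide and any phytochemical known to
occur in the pest's host plants.  That index (in [0, 1], with 1 meaning an
identical feature set — e.g. a synthetic pyrethroid versus a pyrethrin) is
the chemical predictor fed into the survival models.

Fingerprints are hashed linear-path (topological) fingerprints: every bond
path up to a maximum length is hashed onto a fixed-length bit vector, so two
molecules sharing many substructural paths share many bits.  The algorithm
and bit length are configurable; similarity and the diet-max index are
computed here, with RDKit supplying only SMILES parsing and the fingerprint
bits themselves.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

# RDKit writes parse diagnostics to its own log; failures are surfaced as
# SmilesError / exclusion-ledger rows instead.
RDLogger.DisableLog("rdApp.*")

__all__ = [
    "Compound",
    "FingerprintConfig",
    "SimilarityIndex",
    "SmilesError",
    "parse_smiles",
    "fingerprint",
    "fingerprint_smiles",
    "tanimoto",
    "diet_similarity_index",
    "build_similarity_table",
    "similarity_by_moa_summary",
]


class SmilesError(ValueError):
    """A SMILES string that is empty or cannot be parsed into a molecule."""


@dataclass(frozen=True)
class Compound:
    """A chemical with a unique label, a SMILES structure and a role."""

    id: str
    smiles: str
    kind: str  # "insecticide" | "phytochemical"


@dataclass(frozen=True)
class FingerprintConfig:
    """Parameters of the hashed path fingerprint.

    n_bits
        Length of the binary vector; must be identical across any set of
        fingerprints that will be compared.
    max_path
        Longest bond path (in bonds) hashed into the vector.
    """

    n_bits: int = 1024
    max_path: int = 7

    def __post_init__(self) -> None:
        if self.n_bits < 64:
            raise ValueError("fingerprint length must be >= 64 bits")
        if self.max_path < 1:
            raise ValueError("max_path must be >= 1")


@dataclass(frozen=True)
class SimilarityIndex:
    """Maximum insecticide-diet similarity for one pest x insecticide pair."""

    pest_id: str
    insecticide_id: str
    score: float
    closest_phytochemical_id: str


def parse_smiles(text: str) -> Chem.Mol:
    """Parse a SMILES string into an RDKit molecule.

    Raises :class:`SmilesError` for empty or unparseable input; callers that
    process compound tables catch this and record the compound in an
    exclusion ledger rather than dropping it silently.
    """
    if not text or not text.strip():
        raise SmilesError("empty SMILES string")
    mol = Chem.MolFromSmiles(text)
    if mol is None:
        raise SmilesError(f"unparseable SMILES: {text!r}")
    return mol


def fingerprint(mol: Chem.Mol, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Hashed linear-path fingerprint of a molecule as a boolean vector.

    Deterministic: identical molecular graphs give bitwise-identical
    fingerprints.
    """
    bv = Chem.RDKFingerprint(
        mol, minPath=1, maxPath=config.max_path, fpSize=config.n_bits, nBitsPerHash=2
    )
    bits = np.zeros(config.n_bits, dtype=bool)
    bits[list(bv.GetOnBits())] = True
    return bits


def fingerprint_smiles(smiles: str, config: FingerprintConfig = FingerprintConfig()) -> np.ndarray:
    """Parse a SMILES string and fingerprint it in one step."""
    return fingerprint(parse_smiles(smiles), config)


def tanimoto(a: np.ndarray, b: np.ndarray) -> float:
    """Tanimoto (Jaccard) similarity |a AND b| / |a OR b| of two bit vectors.

    Symmetric, in [0, 1], and 1 exactly when the set-bit sets coincide.  Two
    all-zero fingerprints share no features to compare; by convention the
    similarity is 0 (with a warning) so a feature-free compound can never
    inflate the diet-max index.
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("Tanimoto of two all-zero fingerprints defined as 0", stacklevel=2)
        return 0.0
    return np.count_nonzero(a & b) / union


def diet_similarity_index(
    insecticide_id: str,
    diet_phytochemical_ids: Iterable[str],
    fingerprints: Mapping[str, np.ndarray],
) -> SimilarityIndex:
    """Maximum Tanimoto similarity between an insecticide and a diet set.

    ``fingerprints`` maps compound ids (the insecticide and every
    phytochemical) to bit vectors of a common length.  Ties on the maximum
    are broken by lexicographic phytochemical id so the closest-match label
    is reproducible.
    """
    diet_ids = sorted(set(diet_phytochemical_ids))
    if not diet_ids:
        raise ValueError(f"empty usable diet set for insecticide {insecticide_id!r}")
    fp_ins = fingerprints[insecticide_id]
    best_id, best_score = None, -1.0
    for pid in diet_ids:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            s = tanimoto(fp_ins, fingerprints[pid])
        if s > best_score:
            best_id, best_score = pid, s
    return SimilarityIndex(
        pest_id="",
        insecticide_id=insecticide_id,
        score=best_score,
        closest_phytochemical_id=best_id,
    )


def build_similarity_table(
    compounds: pd.DataFrame,
    diet: pd.DataFrame,
    config: FingerprintConfig = FingerprintConfig(),
    fingerprints: Mapping[str, np.ndarray] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per pest x insecticide maximum-similarity table plus exclusion ledger.

    Parameters
    ----------
    compounds
        Columns ``id, smiles, kind`` with kind in {insecticide,
        phytochemical}.  Compounds whose SMILES cannot be parsed are recorded
        in the exclusion ledger and left out of every diet set (mirroring
        curation pipelines where only about half of catalogued
        phytochemicals have a usable structure).
    diet
        Columns ``pest_id, phytochemical_id``: host-plant phytochemical
        occurrences per pest species.
    fingerprints
        Optional precomputed id -> bit-vector mapping (e.g. synthetic
        fingerprints); when given, SMILES are ignored for those ids.

    Returns
    -------
    (similarity, exclusions)
        ``similarity`` has columns ``pest_id, insecticide_id, score,
        closest_phytochemical_id``; ``exclusions`` has ``id, reason``.
    """
    fps: dict[str, np.ndarray] = dict(fingerprints or {})
    exclusions: list[dict] = []
    for row in compounds.itertuples(index=False):
        if row.id in fps:
            continue
        try:
            fps[row.id] = fingerprint_smiles(row.smiles, config)
        except SmilesError as exc:
            exclusions.append({"id": row.id, "reason": str(exc)})

    kinds = compounds.set_index("id")["kind"]
    insecticide_ids = sorted(i for i in kinds[kinds == "insecticide"].index if i in fps)
    rows: list[dict] = []
    for pest_id, grp in diet.groupby("pest_id", sort=True):
        usable = sorted(p for p in grp["phytochemical_id"].unique() if p in fps)
        if not usable:
            exclusions.append(
                {"id": str(pest_id), "reason": "no usable diet phytochemicals after SMILES exclusions"}
            )
            continue
        for ins in insecticide_ids:
            idx = diet_similarity_index(ins, usable, fps)
            rows.append(
                {
                    "pest_id": pest_id,
                    "insecticide_id": ins,
                    "score": idx.score,
                    "closest_phytochemical_id": idx.closest_phytochemical_id,
                }
            )
    similarity = pd.DataFrame(rows, columns=["pest_id", "insecticide_id", "score", "closest_phytochemical_id"])
    ledger = pd.DataFrame(exclusions, columns=["id", "reason"])
    return similarity, ledger


def similarity_by_moa_summary(
    similarity: pd.DataFrame, moa_map: Mapping[str, str]
) -> pd.DataFrame:
    """Distribution of maximum similarities per insecticide mode-of-action class.

    Returns one row per MoA class with min/quartiles/max (the numbers a
    boxplot of the similarity index grouped by MoA would draw), plus a
    ``__all__`` row giving the global range.
    """
    df = similarity.copy()
    missing = sorted(set(df["insecticide_id"]) - set(moa_map))
    if missing:
        raise KeyError(f"insecticides with no MoA class: {missing}")
    df["moa_class"] = df["insecticide_id"].map(moa_map)

    def _summ(s: pd.Series) -> pd.Series:
        q = s.quantile([0.0, 0.25, 0.5, 0.75, 1.0])
        return pd.Series(
            {"n": len(s), "min": q[0.0], "q1": q[0.25], "median": q[0.5], "q3": q[0.75], "max": q[1.0]}
        )

    out = df.groupby("moa_class")["score"].apply(_summ).unstack()
    out.loc["__all__"] = _summ(df["score"])
    out["n"] = out["n"].astype(int)
    return out.reset_index().rename(columns={"index": "moa_class"})
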