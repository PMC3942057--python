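"""Annotation of extracted signatures against named archetypes,
cohort signature profiles, and dominant-sample (outlier) detection."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .errors import ValidationError
from .nmf import ExposureMatrix, SignatureSet
from .synthetic import ArchetypeLibrary


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two non-negative spectra; in [0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError("inputs must be 1-D vectors of equal length")
    if np.any(a < 0) or np.any(b < 0):
        raise ValidationError("inputs must be non-negative")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValidationError("cosine similarity undefined for the zero vector")
    return float(np.clip(a @ b / (na * nb), 0.0, 1.0))


@dataclass
class SignatureAnnotation:
    """Per-signature best-archetype assignment with similarities."""

    table: pd.DataFrame  # signature_id, archetype, cosine, matched, exclusive

    def best(self, signature_id: str) -> tuple[str, float]:
        row = self.table[self.table["signature_id"] == signature_id]
        if row.empty:
            raise ValidationError(f"unknown signature {signature_id!r}")
        return str(row.iloc[0]["archetype"]), float(row.iloc[0]["cosine"])

    def matched_archetypes(self) -> set[str]:
        return set(self.table.loc[self.table["matched"], "archetype"])

    @property
    def n_unmatched(self) -> int:
        return int((~self.table["matched"]).sum())

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def match_signatures(
    signatures: SignatureSet | np.ndarray,
    archetypes: ArchetypeLibrary,
    threshold: float = 0.8,
) -> SignatureAnnotation:
    """Assign each extracted signature an archetype.

    A one-to-one assignment maximizing total cosine similarity covers
    min(r, #archetypes) signatures; any surplus signatures are matched
    greedily to their best archetype and flagged non-exclusive. A signature
    is "matched" when its similarity clears ``threshold``.
    """
    if isinstance(signatures, SignatureSet):
        W = signatures.W
        sig_ids = signatures.signature_ids
        if tuple(signatures.scheme.labels) != tuple(archetypes.scheme.labels):
            raise ValidationError("signature and archetype category schemes differ")
    else:
        W = np.asarray(signatures, dtype=float)
        sig_ids = [f"sig{c + 1}" for c in range(W.shape[1])]
    names = archetypes.names
    A = archetypes.matrix(names)
    r, a = W.shape[1], len(names)
    sim = np.array([[cosine_similarity(W[:, i], A[:, j]) for j in range(a)] for i in range(r)])

    assigned: dict[int, int] = {}
    rows_idx, cols_idx = linear_sum_assignment(-sim)
    for i, j in zip(rows_idx, cols_idx):
        assigned[int(i)] = int(j)
    exclusive = {i: True for i in assigned}
    for i in range(r):
        if i not in assigned:  # r > #archetypes: greedy, non-exclusive
            assigned[i] = int(np.argmax(sim[i]))
            exclusive[i] = False

    # flag archetypes hit by more than one signature
    hit_counts: dict[int, int] = {}
    for j in assigned.values():
        hit_counts[j] = hit_counts.get(j, 0) + 1

    records = []
    for i in range(r):
        j = assigned[i]
        records.append(
            {
                "signature_id": sig_ids[i],
                "archetype": names[j],
                "cosine": sim[i, j],
                "matched": bool(sim[i, j] >= threshold),
                "exclusive": bool(exclusive[i] and hit_counts[j] == 1),
            }
        )
    return SignatureAnnotation(table=pd.DataFrame.from_records(records))


@dataclass
class SignatureProfile:
    """The set of archetypes present in a cohort, plus private signatures."""

    cohort: str
    archetypes: frozenset[str]
    n_unmatched: int = 0

    def __eq__(self, other) -> bool:  # profile identity = archetype set identity
        if not isinstance(other, SignatureProfile):
            return NotImplemented
        return self.archetypes == other.archetypes

    def to_dict(self) -> dict:
        return {
            "cohort": self.cohort,
            "archetypes": sorted(self.archetypes),
            "n_unmatched": self.n_unmatched,
        }


def build_profile(annotation: SignatureAnnotation, cohort: str) -> SignatureProfile:
    return SignatureProfile(
        cohort=cohort,
        archetypes=frozenset(annotation.matched_archetypes()),
        n_unmatched=annotation.n_unmatched,
    )


def detect_outlier_samples(
    exposures: ExposureMatrix,
    signature_id: str,
    dominance_threshold: float = 0.5,
) -> list[tuple[str, float]]:
    """Samples holding more than ``dominance_threshold`` of the cohort's
    total raw exposure to one signature, sorted by share descending."""
    if signature_id not in exposures.signature_ids:
        raise ValidationError(f"unknown signature {signature_id!r}")
    if not (0.0 < dominance_threshold < 1.0):
        raise ValidationError("dominance_threshold must be in (0, 1)")
    row = exposures.row(signature_id)
    total = row.sum()
    if total <= 0:
        return []
    shares = row / total
    hits = [
        (exposures.sample_ids[j], float(shares[j]))
        for j in np.argsort(-shares, kind="stable")
        if shares[j] > dominance_threshold
    ]
    return hits
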