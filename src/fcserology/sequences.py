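"""Viral divergence and diversity from aligned nucleotide sequences.

Distances are uncorrected p-distances — the proportion of differing
sites between two aligned sequences, with columns containing a gap
(``-``) or ambiguous base (``N``) excluded.  Divergence is measured
against a named antigen reference sequence; intra-host diversity is the
mean p-distance over all unordered pairs within a subject's sequence
set.  No multiple-hit correction is applied.

Alignment is upstream (e.g. MUSCLE); inputs must already share one
coordinate frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import ConfigurationError, DegenerateInputError, InputError

ALPHABET = frozenset("ACGTN-")
EXCLUDED = frozenset("N-")


@dataclass
class AlignedSequenceSet:
    """Equal-length nucleotide sequences with id metadata.

    Ids follow ``subject|timepoint|clone`` (configurable delimiter);
    missing fields are tolerated and reported as empty strings.
    """

    ids: list[str]
    sequences: list[str]
    metadata: dict = field(default_factory=dict)
    delimiter: str = "|"

    def __post_init__(self) -> None:
        if not self.sequences:
            raise InputError("empty sequence set")
        if len(self.ids) != len(self.sequences):
            raise InputError("ids and sequences must have equal length")
        length = len(self.sequences[0])
        cleaned = []
        for sid, seq in zip(self.ids, self.sequences):
            s = seq.upper()
            if len(s) != length:
                raise InputError(
                    f"sequence {sid!r} has length {len(s)}, expected {length}")
            bad = set(s) - ALPHABET
            if bad:
                raise InputError(
                    f"sequence {sid!r} contains invalid characters {sorted(bad)}")
            cleaned.append(s)
        self.sequences = cleaned

    @property
    def alignment_length(self) -> int:
        return len(self.sequences[0])

    def __len__(self) -> int:
        return len(self.sequences)

    def subject_of(self, seq_id: str) -> str:
        return seq_id.split(self.delimiter)[0]

    def timepoint_of(self, seq_id: str) -> str:
        parts = seq_id.split(self.delimiter)
        return parts[1] if len(parts) > 1 else ""

    def subset(self, subject: str | None = None,
               timepoint: str | None = None) -> "AlignedSequenceSet":
        keep = [
            i for i, sid in enumerate(self.ids)
            if (subject is None or self.subject_of(sid) == subject)
            and (timepoint is None or self.timepoint_of(sid) == str(timepoint))
        ]
        if not keep:
            raise InputError("subset selects no sequences")
        return AlignedSequenceSet(
            [self.ids[i] for i in keep], [self.sequences[i] for i in keep],
            delimiter=self.delimiter)

    @classmethod
    def from_fasta(cls, path, delimiter: str = "|") -> "AlignedSequenceSet":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise InputError(f"no FASTA records in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records],
                   delimiter=delimiter)

    def to_fasta(self, path) -> None:
        records = [SeqRecord(Seq(s), id=i, description="")
                   for i, s in zip(self.ids, self.sequences)]
        SeqIO.write(records, str(path), "fasta")


@dataclass(frozen=True)
class DistanceResult:
    pair: tuple[str, str]
    compared_sites: int
    differing_sites: int

    @property
    def percent_difference(self) -> float:
        return 100.0 * self.differing_sites / self.compared_sites

    @property
    def p_distance(self) -> float:
        return self.differing_sites / self.compared_sites


def percent_divergence(seq: str, reference: str,
                       ids: tuple[str, str] = ("query", "reference")) -> DistanceResult:
    """p-distance (as %) between two aligned sequences, pairwise deletion.

    Columns where either sequence carries a gap or N are excluded before
    counting differences.
    """
    a = seq.upper()
    b = reference.upper()
    if len(a) != len(b):
        raise InputError("sequences must share the aligned length")
    compared = 0
    differing = 0
    for ca, cb in zip(a, b):
        if ca in EXCLUDED or cb in EXCLUDED:
            continue
        if ca not in ALPHABET or cb not in ALPHABET:
            raise InputError(f"invalid characters {ca!r}/{cb!r}")
        compared += 1
        if ca != cb:
            differing += 1
    if compared == 0:
        raise DegenerateInputError("no comparable (gap/N-free) sites")
    return DistanceResult(ids, compared, differing)


def _complete_deletion_columns(seqs: list[str]) -> list[int]:
    length = len(seqs[0])
    return [j for j in range(length)
            if all(s[j] not in EXCLUDED for s in seqs)]


def mean_pairwise_distance(seq_set: AlignedSequenceSet,
                           deletion: str = "pairwise") -> float:
    """Mean p-distance (proportion, 0-1) over all unordered pairs.

    ``deletion="pairwise"`` drops gap/N columns per pair (default);
    ``"complete"`` drops any column with a gap/N in any sequence first.
    """
    if len(seq_set) < 2:
        raise InputError("need >= 2 sequences for a pairwise distance")
    if deletion not in ("pairwise", "complete"):
        raise InputError("deletion must be 'pairwise' or 'complete'")
    seqs = seq_set.sequences
    if deletion == "complete":
        cols = _complete_deletion_columns(seqs)
        if not cols:
            raise DegenerateInputError("no gap/N-free columns")
        seqs = ["".join(s[j] for j in cols) for s in seqs]
    dists = [
        percent_divergence(seqs[i], seqs[j]).p_distance
        for i, j in combinations(range(len(seqs)), 2)
    ]
    return float(np.mean(dists))


def divergence_report(sets: dict[str, AlignedSequenceSet],
                      references: dict[str, str]) -> pd.DataFrame:
    """Mean % divergence of each subject's sequences from each reference.

    One row per subject x reference; all sequence sets and references
    must already share the aligned coordinate frame.
    """
    if not references:
        raise ConfigurationError("no reference sequences supplied")
    rows = []
    for subject, seq_set in sets.items():
        for ref_name, ref_seq in references.items():
            if len(ref_seq) != seq_set.alignment_length:
                raise ConfigurationError(
                    f"reference {ref_name!r} not aligned to subject "
                    f"{subject!r} ({len(ref_seq)} vs {seq_set.alignment_length})")
            pct = [percent_divergence(s, ref_seq).percent_difference
                   for s in seq_set.sequences]
            rows.append({
                "subject": subject,
                "reference": ref_name,
                "n_sequences": len(seq_set),
                "mean_percent_divergence": float(np.mean(pct)),
            })
    return pd.DataFrame(rows)


def diversity_report(seq_set: AlignedSequenceSet,
                     deletion: str = "pairwise") -> pd.DataFrame:
    """Per subject x timepoint mean pairwise p-distance (%).

    Subjects/timepoints are parsed from the sequence ids; groups with a
    single sequence are skipped (diversity undefined).
    """
    keys = sorted({(seq_set.subject_of(i), seq_set.timepoint_of(i))
                   for i in seq_set.ids})
    rows = []
    for subject, tp in keys:
        sub = seq_set.subset(subject=subject, timepoint=tp or None)
        if len(sub) < 2:
            continue
        rows.append({
            "subject": subject,
            "timepoint": tp,
            "n_sequences": len(sub),
            "mean_pairwise_distance_pct":
                100.0 * mean_pairwise_distance(sub, deletion=deletion),
        })
    return pd.DataFrame(rows)
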