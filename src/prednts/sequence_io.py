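"""Sequence and site-label I/O, window extraction, redundancy reduction, splits.

Proteins are read from FASTA; candidate sites are the tyrosine (Y) residues.
Each Y yields a fixed-length window of 2*w+1 residues centred on it, padded
with ``-`` beyond the protein termini.  Positions are 1-based everywhere a
user sees them (site tables, reports); internal indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AA20 = "ACDEFGHIKLMNPQRSTVWY"
GAP = "-"
#: residues outside the 20-letter alphabet are mapped to this placeholder
UNKNOWN = "X"
_NONSTANDARD = set("BJOUZ")

POSITIVE = "positive"
NEGATIVE = "negative"
UNLABELLED = "unknown"


class FastaFormatError(ValueError):
    """Raised for malformed FASTA input."""


class SiteTableError(ValueError):
    """Raised when a site table disagrees with the sequences it annotates."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein sequence with any non-standard letters flagged.

    ``sequence`` is uppercase over the 20 standard letters plus ``X``;
    ``nonstandard`` records the original letters that were mapped to ``X``.
    """

    id: str
    sequence: str
    nonstandard: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if len(self.sequence) < 1:
            raise ValueError(f"protein {self.id!r}: empty sequence")


@dataclass(frozen=True)
class SiteWindow:
    """A 2*w+1 residue window centred on a tyrosine.

    ``center_position`` is the 1-based index of the central Y in the parent
    protein.  ``residues`` uses ``-`` only as terminal padding.
    """

    protein_id: str
    center_position: int
    residues: str
    label: str = UNLABELLED

    def __post_init__(self) -> None:
        n = len(self.residues)
        if n % 2 != 1:
            raise ValueError(f"window length {n} is not odd")
        w = n // 2
        if self.residues[w] != "Y":
            raise ValueError(
                f"{self.protein_id}:{self.center_position}: centre residue is "
                f"{self.residues[w]!r}, expected 'Y'"
            )
        core = self.residues.strip(GAP)
        if GAP in core:
            raise ValueError(
                f"{self.protein_id}:{self.center_position}: internal gap in window"
            )
        if self.label not in (POSITIVE, NEGATIVE, UNLABELLED):
            raise ValueError(f"bad label {self.label!r}")

    @property
    def w(self) -> int:
        return len(self.residues) // 2


@dataclass(frozen=True)
class DatasetSplit:
    """Balanced training windows plus an unbalanced held-out partition."""

    training: tuple[SiteWindow, ...]
    independent: tuple[SiteWindow, ...]
    split_seed: int


def _clean_sequence(raw: str, record_id: str) -> tuple[str, frozenset[str]]:
    seq = raw.upper()
    flagged = {c for c in seq if c in _NONSTANDARD or c == UNKNOWN}
    bad = [c for c in set(seq) if c not in AA20 and c not in _NONSTANDARD and c != UNKNOWN]
    if bad:
        raise FastaFormatError(
            f"record {record_id!r}: illegal sequence characters {sorted(bad)}"
        )
    if flagged - {UNKNOWN}:
        warnings.warn(
            f"record {record_id!r}: non-standard residues "
            f"{sorted(flagged - {UNKNOWN})} mapped to 'X'",
            stacklevel=3,
        )
        for c in _NONSTANDARD:
            seq = seq.replace(c, UNKNOWN)
    return seq, frozenset(flagged)


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read proteins from a FASTA file, uppercasing and order-preserving.

    Non-standard residues (B, J, O, U, Z) are mapped to ``X`` with a warning.
    An empty file yields an empty list.
    """
    records: list[ProteinRecord] = []
    for i, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        if not rec.id:
            raise FastaFormatError(f"{path}: record {i} has an empty header")
        seq = str(rec.seq)
        if not seq:
            raise FastaFormatError(f"{path}: record {rec.id!r} has an empty sequence")
        cleaned, flagged = _clean_sequence(seq, rec.id)
        records.append(ProteinRecord(id=rec.id, sequence=cleaned, nonstandard=flagged))
    return records


def write_fasta(records: Iterable[ProteinRecord], path_or_handle) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    if isinstance(path_or_handle, (str, Path)):
        SeqIO.write(seqrecs, str(path_or_handle), "fasta")
    else:
        SeqIO.write(seqrecs, path_or_handle, "fasta")


def extract_windows(protein: ProteinRecord, w: int = 20) -> list[SiteWindow]:
    """One window of length 2*w+1 per Y in the protein, padded with ``-``."""
    if w < 1:
        raise ValueError("w must be >= 1")
    seq = protein.sequence
    padded = GAP * w + seq + GAP * w
    out = []
    for i, aa in enumerate(seq):
        if aa == "Y":
            out.append(
                SiteWindow(
                    protein_id=protein.id,
                    center_position=i + 1,
                    residues=padded[i : i + 2 * w + 1],
                )
            )
    return out


def read_site_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV site table with columns protein_id, position, label (1/0)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str})
    required = {"protein_id", "position", "label"}
    missing = required - set(df.columns)
    if missing:
        raise SiteTableError(f"{path}: missing columns {sorted(missing)}")
    if not df["label"].isin([0, 1]).all():
        raise SiteTableError(f"{path}: labels must be 0 or 1")
    return df


def write_site_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def attach_labels(
    windows: Sequence[SiteWindow], site_table: pd.DataFrame
) -> list[SiteWindow]:
    """Label windows from a site table.

    Positions listed with label 1 become positive; every other Y of a protein
    that appears in the table becomes negative; proteins absent from the table
    keep the ``unknown`` label.  A listed position that does not correspond to
    a Y window is a validation error.
    """
    known_centers = {(sw.protein_id, sw.center_position) for sw in windows}
    proteins_in_windows = {sw.protein_id for sw in windows}
    positives: set[tuple[str, int]] = set()
    listed_proteins: set[str] = set()
    offenders: list[str] = []
    for row in site_table.itertuples(index=False):
        pid, pos, label = str(row.protein_id), int(row.position), int(row.label)
        listed_proteins.add(pid)
        if pid in proteins_in_windows and (pid, pos) not in known_centers:
            offenders.append(f"{pid}:{pos}")
            continue
        if label == 1:
            positives.add((pid, pos))
    if offenders:
        raise SiteTableError(
            "site table positions do not point at Y residues: "
            + ", ".join(offenders)
        )
    out = []
    for sw in windows:
        if sw.protein_id not in listed_proteins:
            out.append(sw)
        elif (sw.protein_id, sw.center_position) in positives:
            out.append(replace(sw, label=POSITIVE))
        else:
            out.append(replace(sw, label=NEGATIVE))
    return out


def window_identity(a: str, b: str) -> float:
    """Fraction of matching positions; ``-`` matches only ``-``."""
    if len(a) != len(b):
        raise ValueError("windows must share length")
    return sum(x == y for x, y in zip(a, b)) / len(a)


def reduce_redundancy(
    windows: Sequence[SiteWindow],
    identity_threshold: float = 0.4,
    cluster_file: str | Path | None = None,
) -> list[SiteWindow]:
    """Greedy longest-first clustering on window strings; keep one per cluster.

    Two windows cluster together when their positionwise identity (gap
    positions count as mismatch unless both are ``-``) reaches the threshold.
    Alternatively, ``cluster_file`` ingests an externally produced CD-HIT
    ``.clstr`` file and keeps each cluster's representative.
    """
    if cluster_file is not None:
        keep_ids = _parse_cdhit_clstr(cluster_file)
        return [sw for sw in windows if sw.protein_id in keep_ids]
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(
        range(len(windows)),
        key=lambda i: (-len(windows[i].residues.strip(GAP)), i),
    )
    rep_idx: list[int] = []
    for i in order:
        sw = windows[i]
        if all(
            window_identity(sw.residues, windows[j].residues) < identity_threshold
            for j in rep_idx
        ):
            rep_idx.append(i)
    return [windows[i] for i in sorted(rep_idx)]


def _parse_cdhit_clstr(path: str | Path) -> set[str]:
    reps: set[str] = set()
    with open(path) as fh:
        for line in fh:
            if line.startswith(">"):
                continue
            if line.rstrip().endswith("*"):
                name = line.split(">", 1)[1].split("...", 1)[0]
                reps.add(name)
    return reps


def make_split(
    windows: Sequence[SiteWindow],
    independent_fraction: float = 0.2,
    seed: int = 0,
) -> DatasetSplit:
    """Hold out a fraction of each class, then balance the remainder 1:1.

    The independent partition keeps its natural class imbalance; the training
    partition down-samples the majority class uniformly at random from the
    same seeded stream.
    """
    if not 0 <= independent_fraction < 1:
        raise ValueError("independent_fraction must be in [0, 1)")
    pos = [sw for sw in windows if sw.label == POSITIVE]
    neg = [sw for sw in windows if sw.label == NEGATIVE]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError(
            f"need >= 2 windows per class, got {len(pos)} positive / {len(neg)} negative"
        )
    rng = np.random.default_rng(seed)
    n_ind_pos = int(len(pos) * independent_fraction)
    n_ind_neg = int(len(neg) * independent_fraction)
    if independent_fraction > 0 and (
        len(pos) - n_ind_pos < 1 or len(neg) - n_ind_neg < 1
    ):
        raise ValueError("too few samples to form both partitions")
    ind_pos_idx = set(rng.choice(len(pos), size=n_ind_pos, replace=False).tolist())
    ind_neg_idx = set(rng.choice(len(neg), size=n_ind_neg, replace=False).tolist())
    train_pos = [sw for i, sw in enumerate(pos) if i not in ind_pos_idx]
    train_neg = [sw for i, sw in enumerate(neg) if i not in ind_neg_idx]
    # balance 1:1 by down-sampling the majority class
    n_bal = min(len(train_pos), len(train_neg))
    if len(train_pos) > n_bal:
        keep = set(rng.choice(len(train_pos), size=n_bal, replace=False).tolist())
        train_pos = [sw for i, sw in enumerate(train_pos) if i in keep]
    if len(train_neg) > n_bal:
        keep = set(rng.choice(len(train_neg), size=n_bal, replace=False).tolist())
        train_neg = [sw for i, sw in enumerate(train_neg) if i in keep]
    independent = tuple(
        [sw for i, sw in enumerate(pos) if i in ind_pos_idx]
        + [sw for i, sw in enumerate(neg) if i in ind_neg_idx]
    )
    return DatasetSplit(
        training=tuple(train_pos + train_neg),
        independent=independent,
        split_seed=seed,
    )


def windows_to_frame(windows: Sequence[SiteWindow]) -> pd.DataFrame:
    """Window export: protein_id, position (1-based), window, label."""
    return pd.DataFrame(
        {
            "protein_id": [sw.protein_id for sw in windows],
            "position": [sw.center_position for sw in windows],
            "window": [sw.residues for sw in windows],
            "label": [sw.label for sw in windows],
        }
    )


def labels_array(windows: Sequence[SiteWindow]) -> np.ndarray:
    """0/1 label vector; raises if any window is unlabelled."""
    if any(sw.label == UNLABELLED for sw in windows):
        raise ValueError("unlabelled windows present")
    return np.array([1 if sw.label == POSITIVE else 0 for sw in windows])
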