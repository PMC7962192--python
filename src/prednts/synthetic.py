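"""Synthetic nitroprotein generator with a planted compositional motif.

Proteins are drawn i.i.d. from a background amino-acid distribution
(uniform over the 20 letters by default).  Each tyrosine becomes a positive
site with probability ``positive_fraction``; the flanking residues of
positive sites (offsets -5..+5 by default, centre excluded) are then
redrawn from a motif-boosted distribution: multiplicative factors
``exp(+effect_size)`` for the enriched letters (K, R, E — the charged
residues over-represented around genuine nitration sites) and
``exp(-effect_size)`` for the depleted ones (Y, S, F, L), renormalized.

Only non-Y flank positions are resampled, and Y is excluded from the
resampling alphabet, so the set of tyrosines — and hence the site table —
is unaffected by planting.  At ``effect_size = 0`` the resampling
distribution equals the background conditional on non-Y, which is exactly
the law those positions already follow: positives and negatives are then
identically distributed.

What this emulates: a localized compositional preference around modified
sites over an otherwise memoryless sequence.  What it does not emulate:
homology between proteins, positional correlations, or realistic proteome
composition; results on it bound pipeline correctness, not real-data
performance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .sequence_io import AA20, ProteinRecord, SiteWindow, attach_labels, extract_windows

#: flank offsets carrying the planted motif (centre 0 excluded)
DEFAULT_MOTIF_OFFSETS = tuple(o for o in range(-5, 6) if o != 0)
DEFAULT_ENRICHED = ("K", "R", "E")
DEFAULT_DEPLETED = ("Y", "S", "F", "L")


@dataclass(frozen=True)
class SyntheticConfig:
    n_proteins: int = 150
    length_range: tuple[int, int] = (60, 140)
    background_freqs: Mapping[str, float] | None = None  # None -> uniform
    enriched: tuple[str, ...] = DEFAULT_ENRICHED
    depleted: tuple[str, ...] = DEFAULT_DEPLETED
    motif_offsets: tuple[int, ...] = DEFAULT_MOTIF_OFFSETS
    positive_fraction: float = 0.35
    effect_size: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.positive_fraction < 1:
            raise ValueError("positive_fraction must be in (0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.length_range[0] < 3 or self.length_range[0] > self.length_range[1]:
            raise ValueError(f"bad length_range {self.length_range}")
        if self.background_freqs is not None:
            total = sum(self.background_freqs.get(a, 0.0) for a in AA20)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("background_freqs must sum to 1 over the 20 letters")

    def background_vector(self) -> np.ndarray:
        if self.background_freqs is None:
            return np.full(20, 1 / 20)
        return np.array([self.background_freqs[a] for a in AA20])

    def motif_vector(self) -> np.ndarray:
        """Boosted letter distribution over AA20 (before conditioning)."""
        boost = np.ones(20)
        for a in self.enriched:
            boost[AA20.index(a)] = np.exp(self.effect_size)
        for a in self.depleted:
            boost[AA20.index(a)] = np.exp(-self.effect_size)
        v = self.background_vector() * boost
        return v / v.sum()


def generate(config: SyntheticConfig) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """Draw proteins and a site table labelling every Y, deterministically."""
    rng = np.random.default_rng(config.seed)
    letters = np.array(list(AA20))
    bg = config.background_vector()
    motif = config.motif_vector()
    y_idx = AA20.index("Y")
    # resampling law: motif-boosted, conditioned on not producing a new Y
    motif_non_y = motif.copy()
    motif_non_y[y_idx] = 0.0
    if motif_non_y.sum() == 0:
        raise ValueError("motif distribution degenerate: only Y has mass")
    motif_non_y /= motif_non_y.sum()

    proteins: list[ProteinRecord] = []
    rows: list[tuple[str, int, int]] = []
    for p in range(config.n_proteins):
        length = int(
            rng.integers(config.length_range[0], config.length_range[1] + 1)
        )
        seq = rng.choice(letters, size=length, p=bg)
        y_positions = np.flatnonzero(seq == "Y")
        is_pos = rng.random(len(y_positions)) < config.positive_fraction
        for i, planted in zip(y_positions, is_pos):
            if not planted:
                continue
            for off in config.motif_offsets:
                j = i + off
                if 0 <= j < length and seq[j] != "Y":
                    seq[j] = rng.choice(letters, p=motif_non_y)
        pid = f"syn{p:04d}"
        proteins.append(ProteinRecord(id=pid, sequence="".join(seq)))
        for i, planted in zip(y_positions, is_pos):
            rows.append((pid, int(i) + 1, int(planted)))
    sites = pd.DataFrame(rows, columns=["protein_id", "position", "label"])
    return proteins, sites


def labelled_windows(
    proteins: Sequence[ProteinRecord], sites: pd.DataFrame, w: int = 20
) -> list[SiteWindow]:
    """Extract and label all Y windows for a generated dataset."""
    windows = [sw for prot in proteins for sw in extract_windows(prot, w)]
    return attach_labels(windows, sites)


FIXTURE_SEED = 20210308
#: frozen counts for the bundled deterministic fixture
FIXTURE_MANIFEST = {"n_proteins": 25, "n_positive": 30, "n_negative": 74}


def fixture_small() -> tuple[list[ProteinRecord], pd.DataFrame, dict]:
    """Tiny deterministic dataset (25 proteins) for tests and docs examples."""
    config = SyntheticConfig(
        n_proteins=25, length_range=(50, 90), seed=FIXTURE_SEED
    )
    proteins, sites = generate(config)
    return proteins, sites, dict(FIXTURE_MANIFEST)
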