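"""Shared genomic containers: genome layout, anchors, dyad maps and fragment sets.

Coordinates are 0-based, half-open throughout the package. An *anchor* is a
single reference point (a replication origin or a TSS); a *dyad* is the centre
of a nucleosome-protected footprint; a *fragment* is a mapped
nucleosome-protected sequencing fragment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import InputError

DEFAULT_FOOTPRINT = 147

#: strand code for unstranded anchors (replication origins)
UNSTRANDED = "."


@dataclass(frozen=True)
class GenomeSpec:
    """Chromosome names and lengths of a (synthetic or real) genome."""

    chrom_names: tuple[str, ...]
    chrom_lengths: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.chrom_names) != len(self.chrom_lengths):
            raise InputError("chrom_names and chrom_lengths differ in length")
        if len(set(self.chrom_names)) != len(self.chrom_names):
            raise InputError("chromosome names must be unique")
        if any(length <= 0 for length in self.chrom_lengths):
            raise InputError("chromosome lengths must be positive")

    @classmethod
    def single(cls, length: int, name: str = "chrI") -> "GenomeSpec":
        return cls((name,), (int(length),))

    @property
    def total_length(self) -> int:
        return int(sum(self.chrom_lengths))

    def length_of(self, chrom: str) -> int:
        try:
            return self.chrom_lengths[self.chrom_names.index(chrom)]
        except ValueError:
            raise InputError(f"unknown chromosome {chrom!r}") from None

    def as_dict(self) -> dict[str, int]:
        return dict(zip(self.chrom_names, self.chrom_lengths))


@dataclass(frozen=True)
class Anchor:
    chrom: str
    position: int
    strand: str = UNSTRANDED


@dataclass
class AnchorSet:
    """A collection of metaprofile anchors of a single kind.

    Origins are unstranded (strand ``.``); TSS carry ``+`` or ``-`` and their
    windows are flipped so that downstream is always positive offset.
    """

    anchors: list[Anchor]
    kind: str = "origin"

    def __len__(self) -> int:
        return len(self.anchors)

    def __iter__(self) -> Iterator[Anchor]:
        return iter(self.anchors)

    def validate(self, genome: GenomeSpec) -> None:
        sizes = genome.as_dict()
        for a in self.anchors:
            if a.chrom not in sizes:
                raise InputError(f"anchor on unknown chromosome {a.chrom!r}")
            if not 0 <= a.position < sizes[a.chrom]:
                raise InputError(
                    f"anchor position {a.position} outside {a.chrom} "
                    f"[0, {sizes[a.chrom]})"
                )


@dataclass
class DyadMap:
    """Per-chromosome sorted nucleosome dyad positions with a common footprint."""

    dyads: dict[str, np.ndarray]
    footprint: int = DEFAULT_FOOTPRINT

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for chrom, pos in self.dyads.items():
            arr = np.asarray(pos, dtype=np.int64)
            if np.any(np.diff(arr) < 0):
                raise InputError(f"dyads on {chrom} are not sorted")
            clean[chrom] = arr
        self.dyads = clean

    @property
    def n_dyads(self) -> int:
        return int(sum(len(v) for v in self.dyads.values()))

    def is_empty(self) -> bool:
        return self.n_dyads == 0


#: canonical column order of a fragment table
FRAGMENT_COLUMNS = ["chrom", "start", "end", "strand", "label", "sample_id"]


@dataclass
class FragmentSet:
    """Mapped nucleosome-protected fragments as a tidy table.

    Columns: chrom, start, end (half-open), strand, label (``nascent`` or
    ``total``) and sample_id.
    """

    table: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=FRAGMENT_COLUMNS)
    )

    def __post_init__(self) -> None:
        missing = [c for c in FRAGMENT_COLUMNS if c not in self.table.columns]
        if missing:
            raise InputError(f"fragment table missing columns {missing}")
        if len(self.table) and not (self.table["start"] < self.table["end"]).all():
            raise InputError("fragment with end <= start")
        self.table = self.table[FRAGMENT_COLUMNS].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.table["sample_id"].unique().tolist())

    def subset(self, label: str | None = None, sample_id: str | None = None) -> "FragmentSet":
        tab = self.table
        if label is not None:
            tab = tab[tab["label"] == label]
        if sample_id is not None:
            tab = tab[tab["sample_id"] == sample_id]
        return FragmentSet(tab.copy())

    @classmethod
    def from_arrays(
        cls,
        chrom: np.ndarray | list,
        start: np.ndarray | list,
        end: np.ndarray | list,
        strand: np.ndarray | list | str = ".",
        label: str = "total",
        sample_id: str = "sample",
    ) -> "FragmentSet":
        n = len(start)
        if isinstance(strand, str):
            strand = [strand] * n
        return cls(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": np.asarray(start, dtype=np.int64),
                    "end": np.asarray(end, dtype=np.int64),
                    "strand": strand,
                    "label": label,
                    "sample_id": sample_id,
                }
            )
        )
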