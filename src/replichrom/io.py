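"""Readers and writers for the plain-text formats the pipeline exchanges.

BED is taken at face value: 0-based, half-open, tab-separated, BED3 or BED6,
no dialect auto-detection. Fragment BED uses the name field for the
nascent/total label; anchor BED uses it for the anchor kind. Profiles, lane
traces and peptide tables are TSV with a header; profile files carry their
parameterization in ``#`` header comments.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from .errors import InputError
from .gel import LaneTrace
from .genome import Anchor, AnchorSet, DyadMap, FragmentSet, UNSTRANDED
from .metaprofile import MetaProfile
from .silac import PeptideRecord


def _parse_bed_lines(path: str | Path) -> Iterable[tuple[int, list[str]]]:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise InputError(f"{path}:{lineno}: fewer than 3 BED fields")
            yield lineno, fields


def _parse_interval(path, lineno: int, fields: list[str]) -> tuple[str, int, int]:
    try:
        start, end = int(fields[1]), int(fields[2])
    except ValueError:
        raise InputError(f"{path}:{lineno}: non-integer coordinates") from None
    if end <= start:
        raise InputError(f"{path}:{lineno}: end {end} <= start {start}")
    if start < 0:
        raise InputError(f"{path}:{lineno}: negative start")
    return fields[0], start, end


def read_bed_fragments(
    path: str | Path, default_label: str = "total", sample_id: str | None = None
) -> FragmentSet:
    """Read a fragment BED (BED3/BED6). Name field = nascent/total label."""
    chroms, starts, ends, strands, labels = [], [], [], [], []
    for lineno, fields in _parse_bed_lines(path):
        chrom, start, end = _parse_interval(path, lineno, fields)
        label = fields[3] if len(fields) > 3 and fields[3] not in (".", "") else default_label
        if label not in ("nascent", "total"):
            raise InputError(
                f"{path}:{lineno}: fragment label must be nascent/total, got {label!r}"
            )
        strand = fields[5] if len(fields) > 5 else UNSTRANDED
        chroms.append(chrom)
        starts.append(start)
        ends.append(end)
        strands.append(strand)
        labels.append(label)
    sid = sample_id if sample_id is not None else Path(path).stem
    return FragmentSet(
        pd.DataFrame(
            {
                "chrom": chroms,
                "start": np.array(starts, dtype=np.int64),
                "end": np.array(ends, dtype=np.int64),
                "strand": strands,
                "label": labels,
                "sample_id": sid,
            }
        )
    )


def read_bed_anchors(path: str | Path, kind: str = "origin") -> AnchorSet:
    """Read anchors from BED; the anchor point is the interval start."""
    anchors: list[Anchor] = []
    for lineno, fields in _parse_bed_lines(path):
        chrom, start, _end = _parse_interval(path, lineno, fields)
        strand = fields[5] if len(fields) > 5 else UNSTRANDED
        if strand not in ("+", "-", UNSTRANDED):
            raise InputError(f"{path}:{lineno}: bad strand {strand!r}")
        anchors.append(Anchor(chrom, start, strand))
    return AnchorSet(anchors, kind=kind)


def write_bed_fragments(fragments: FragmentSet, path: str | Path) -> None:
    """Write fragments as BED6 (name = label, score = 0)."""
    tab = fragments.table
    with open(path, "w") as fh:
        for row in tab.itertuples(index=False):
            fh.write(
                f"{row.chrom}\t{row.start}\t{row.end}\t{row.label}\t0\t{row.strand}\n"
            )


def write_bed_anchors(anchors: AnchorSet, path: str | Path) -> None:
    """Write anchors as 1-bp BED6 intervals (name = kind, score = 0)."""
    with open(path, "w") as fh:
        for a in anchors:
            fh.write(
                f"{a.chrom}\t{a.position}\t{a.position + 1}\t{anchors.kind}\t0\t{a.strand}\n"
            )


def write_bed_dyads(dyads: DyadMap, path: str | Path) -> None:
    """Write dyads as 1-bp BED intervals."""
    with open(path, "w") as fh:
        for chrom in sorted(dyads.dyads):
            for p in dyads.dyads[chrom]:
                fh.write(f"{chrom}\t{p}\t{p + 1}\tdyad\t0\t.\n")


def write_profile(
    profile: MetaProfile, path: str | Path, format: str = "tsv"
) -> None:
    """Write a metaprofile as TSV (offset, value) or bedGraph-style rows.

    The TSV header comments carry n_anchors, n_excluded, smooth_window,
    flank and the normalization scope.
    """
    if format not in ("tsv", "bedgraph"):
        raise InputError(f"unknown profile format {format!r}")
    with open(path, "w") as fh:
        fh.write(f"# n_anchors={profile.n_anchors}\n")
        fh.write(f"# n_excluded={profile.n_excluded}\n")
        fh.write(f"# smooth_window={profile.smooth_window}\n")
        fh.write(f"# flank={profile.flank}\n")
        fh.write("# normalization=genome-wide mean depth per bp, per sample\n")
        if format == "tsv":
            fh.write("offset\tvalue\n")
            for off, val in zip(profile.offsets, profile.values):
                fh.write(f"{off}\t{val:.12g}\n")
        else:
            for off, val in zip(profile.offsets, profile.values):
                fh.write(f"profile\t{off}\t{off + 1}\t{val:.12g}\n")


def read_profile(path: str | Path) -> MetaProfile:
    """Read a profile TSV written by :func:`write_profile`."""
    meta: dict[str, int] = {}
    offsets: list[int] = []
    values: list[float] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if "=" in body:
                    key, _, val = body.partition("=")
                    try:
                        meta[key.strip()] = int(val)
                    except ValueError:
                        pass
                continue
            if line.startswith("offset") or not line:
                continue
            off_s, val_s = line.split("\t")
            offsets.append(int(off_s))
            values.append(float(val_s))
    flank = meta.get("flank", (len(offsets) - 1) // 2)
    return MetaProfile(
        offsets=np.array(offsets, dtype=np.int64),
        values=np.array(values, dtype=float),
        n_anchors=meta.get("n_anchors", 0),
        n_excluded=meta.get("n_excluded", 0),
        smooth_window=meta.get("smooth_window", 1),
        normalized=True,
        flank=flank,
    )


def write_lane_trace(trace: LaneTrace, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pos, size in trace.ladder:
            fh.write(f"# ladder\t{pos:.6g}\t{size:.6g}\n")
        fh.write("position\tintensity\n")
        for p, i in zip(trace.positions, trace.intensities):
            fh.write(f"{p:.6g}\t{i:.10g}\n")


def read_lane_trace(path: str | Path) -> LaneTrace:
    positions, intensities, ladder = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("# ladder"):
                _, pos_s, size_s = line.split("\t")
                ladder.append((float(pos_s), float(size_s)))
                continue
            if line.startswith(("#", "position")) or not line:
                continue
            try:
                p_s, i_s = line.split("\t")
                positions.append(float(p_s))
                intensities.append(float(i_s))
            except ValueError:
                raise InputError(f"{path}:{lineno}: malformed trace line") from None
    return LaneTrace(
        positions=np.array(positions), intensities=np.array(intensities), ladder=ladder
    )


SILAC_COLUMNS = ["protein", "peptide", "heavy", "light"]


def write_silac_table(records: list[PeptideRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(SILAC_COLUMNS) + "\n")
        for r in records:
            fh.write(
                f"{r.protein_id}\t{r.peptide_id}\t{r.heavy_intensity:.10g}"
                f"\t{r.light_intensity:.10g}\n"
            )


def read_silac_table(path: str | Path) -> list[PeptideRecord]:
    tab = pd.read_csv(path, sep="\t")
    missing = [c for c in SILAC_COLUMNS if c not in tab.columns]
    if missing:
        raise InputError(f"{path}: missing columns {missing}")
    return [
        PeptideRecord(str(r.protein), str(r.peptide), float(r.heavy), float(r.light))
        for r in tab.itertuples(index=False)
    ]


def load_config(path: str | Path) -> dict:
    """Load a YAML/JSON-style config mapping."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise InputError(f"{path}: config must be a mapping")
    return cfg
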