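"""Synthetic inputs with known ground truth for every downstream stage.

The generators emulate the observable layers of a nascent-chromatin study on a
toy genome: anchor annotations (origins, TSS), phased nucleosome arrays around
those anchors with tunable disorganization, nucleosome-protected fragment
populations (mono-, di-nucleosomal and free), electrophoresis lane traces with
a size ladder, and SILAC heavy/light peptide tables with known enrichment
ratios. Each generator is a pure function of its parameters and one integer
seed; sub-streams are derived from the seed with fixed offsets so the outputs
are bit-reproducible.

No sequence-level realism is attempted (no GC bias, no mappability, no reads).
"""

from __future__ import annotations

import numpy as np

from .errors import InfeasibleParameterError, InputError
from .gel import LaneTrace
from .genome import (
    Anchor,
    AnchorSet,
    DyadMap,
    FragmentSet,
    GenomeSpec,
    UNSTRANDED,
)
from .silac import PeptideRecord

# fixed sub-stream offsets so that each generator draws from its own stream
_STREAM_ANNOTATION = 11
_STREAM_DYADS = 23
_STREAM_FRAGMENTS = 37
_STREAM_LANE = 53
_STREAM_SILAC = 71


def _rng(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(np.uint64(seed) + np.uint64(offset))


def _place_with_min_gap(
    rng: np.random.Generator, length: int, n: int, min_gap: int
) -> np.ndarray:
    """n sorted positions uniform in [0, length) with pairwise gaps >= min_gap.

    Standard trick: sample in the shrunken interval and re-add the gaps.
    """
    if n == 0:
        return np.array([], dtype=np.int64)
    slack = length - (n - 1) * min_gap
    if slack < n:
        raise InfeasibleParameterError(
            f"cannot place {n} anchors with min gap {min_gap} in {length} bp"
        )
    base = np.sort(rng.choice(slack, size=n, replace=False))
    return base + min_gap * np.arange(n)


def gen_annotation(
    spec: GenomeSpec,
    n_origins: int,
    n_tss: int,
    min_gap: int,
    seed: int,
) -> tuple[AnchorSet, AnchorSet]:
    """Uniformly placed origin and TSS anchors with a minimum pairwise gap.

    Anchors are apportioned to chromosomes proportionally to length. Origins
    are unstranded; TSS strands are sampled 50/50. The gap constraint applies
    within each anchor kind on each chromosome.
    """
    rng = _rng(seed, _STREAM_ANNOTATION)
    lengths = np.array(spec.chrom_lengths, dtype=float)
    probs = lengths / lengths.sum()

    def place(n_total: int) -> list[tuple[str, int]]:
        if n_total == 0:
            return []
        counts = rng.multinomial(n_total, probs)
        out: list[tuple[str, int]] = []
        for name, length, n in zip(spec.chrom_names, spec.chrom_lengths, counts):
            pos = _place_with_min_gap(rng, length, int(n), min_gap)
            out.extend((name, int(p)) for p in pos)
        return out

    origins = AnchorSet(
        [Anchor(c, p, UNSTRANDED) for c, p in place(n_origins)], kind="origin"
    )
    tss_sites = place(n_tss)
    strands = rng.choice(["+", "-"], size=len(tss_sites))
    tss = AnchorSet(
        [Anchor(c, p, s) for (c, p), s in zip(tss_sites, strands)], kind="tss"
    )
    return origins, tss


def gen_phased_dyads(
    anchors: AnchorSet,
    repeat: int,
    jitter_sd: float,
    n_per_array: int,
    background_density: float,
    spec: GenomeSpec,
    seed: int,
    footprint: int = 147,
) -> DyadMap:
    """Phased nucleosome arrays flanking each anchor, plus Poisson background.

    Dyads sit at anchor +/- (k * repeat + Normal(0, jitter_sd)) for
    k = 1..n_per_array (the anchor itself is nucleosome-depleted). Background
    dyads are uniform at ``background_density`` per kb. Dyads closer than the
    footprint to an earlier-placed dyad are dropped, keeping the map valid
    without rejection sampling; array dyads are placed before background.
    """
    if repeat < footprint:
        raise InputError(f"repeat {repeat} < footprint {footprint}")
    if jitter_sd < 0:
        raise InputError("jitter_sd must be >= 0")
    rng = _rng(seed, _STREAM_DYADS)
    sizes = spec.as_dict()
    placed: dict[str, list[int]] = {c: [] for c in spec.chrom_names}

    order: list[tuple[str, int]] = []  # placement order
    for a in anchors:
        ks = np.arange(1, n_per_array + 1)
        for sign in (+1, -1):
            offs = sign * (ks * repeat + rng.normal(0.0, jitter_sd, size=len(ks)))
            for off in offs:
                p = int(round(a.position + off))
                if 0 <= p < sizes[a.chrom]:
                    order.append((a.chrom, p))
    for chrom in spec.chrom_names:
        lam = background_density * sizes[chrom] / 1000.0
        n_bg = rng.poisson(lam) if lam > 0 else 0
        for p in rng.integers(0, sizes[chrom], size=n_bg):
            order.append((chrom, int(p)))

    import bisect

    for chrom, p in order:
        kept = placed[chrom]
        i = bisect.bisect_left(kept, p)
        if i > 0 and p - kept[i - 1] < footprint:
            continue
        if i < len(kept) and kept[i] - p < footprint:
            continue
        kept.insert(i, p)

    return DyadMap(
        {c: np.array(v, dtype=np.int64) for c, v in placed.items()},
        footprint=footprint,
    )


def gen_fragments(
    dyads: DyadMap,
    n: int,
    size_mean: float,
    size_sd: float,
    mono_weight: float,
    di_weight: float,
    free_weight: float,
    label: str,
    seed: int,
    spec: GenomeSpec | None = None,
    sample_id: str = "synthetic",
) -> FragmentSet:
    """Fragment population mixing mono-, di-nucleosomal and free DNA.

    Mono fragments are centred on single dyads with Normal(size_mean, size_sd)
    lengths; di fragments span two adjacent dyads of one array; free fragments
    are uniform on the genome (requires ``spec``). All fragments are clipped
    to chromosome bounds.
    """
    weights = np.array([mono_weight, di_weight, free_weight], dtype=float)
    if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0):
        raise InputError("class weights must be >= 0 and sum to 1")
    if label not in ("nascent", "total"):
        raise InputError(f"label must be 'nascent' or 'total', got {label!r}")
    if n > 0 and dyads.is_empty() and free_weight == 0:
        raise InputError("no dyads and free_weight=0: nothing to generate from")
    if free_weight > 0 and spec is None:
        raise InputError("free fragments require a GenomeSpec")

    rng = _rng(seed, _STREAM_FRAGMENTS)
    chroms_with_dyads = [c for c, v in dyads.dyads.items() if len(v) > 0]
    if spec is None:
        # bounds inferred from dyads only; clip generously
        sizes = {c: int(dyads.dyads[c].max()) + 1000 for c in chroms_with_dyads}
        chrom_names = chroms_with_dyads
    else:
        sizes = spec.as_dict()
        chrom_names = list(spec.chrom_names)

    # flat views over all chromosomes for vectorized sampling
    all_dyads = (
        np.concatenate([dyads.dyads[c] for c in chroms_with_dyads])
        if chroms_with_dyads
        else np.array([], dtype=np.int64)
    )
    dyad_chrom_idx = (
        np.concatenate(
            [
                np.full(len(dyads.dyads[c]), k, dtype=np.int64)
                for k, c in enumerate(chroms_with_dyads)
            ]
        )
        if chroms_with_dyads
        else np.array([], dtype=np.int64)
    )
    # adjacent dyad pairs (within one chromosome)
    pair_left: list[np.ndarray] = []
    pair_right: list[np.ndarray] = []
    for c in chroms_with_dyads:
        arr = dyads.dyads[c]
        if len(arr) >= 2:
            pair_left.append(arr[:-1])
            pair_right.append(arr[1:])
    pairs_l = np.concatenate(pair_left) if pair_left else np.array([], dtype=np.int64)
    pairs_r = np.concatenate(pair_right) if pair_right else np.array([], dtype=np.int64)
    pair_chrom_idx = (
        np.concatenate(
            [
                np.full(len(dyads.dyads[c]) - 1, k, dtype=np.int64)
                for k, c in enumerate(chroms_with_dyads)
                if len(dyads.dyads[c]) >= 2
            ]
        )
        if pair_left
        else np.array([], dtype=np.int64)
    )
    if di_weight > 0 and len(pairs_l) == 0 and len(all_dyads) == 0 and free_weight == 0:
        raise InputError("di fragments requested but no adjacent dyads exist")

    classes = rng.choice(3, size=n, p=weights)
    lengths = np.maximum(np.round(rng.normal(size_mean, size_sd, size=n)), 1).astype(
        np.int64
    )
    chrom_idx = np.zeros(n, dtype=np.int64)
    start = np.zeros(n, dtype=np.int64)
    end = np.zeros(n, dtype=np.int64)
    chrom_arrays: dict[int, list[str]] = {}

    is_mono = classes == 0
    is_di = classes == 1
    is_free = classes == 2
    if is_di.any() and len(pairs_l) == 0:
        is_mono = is_mono | is_di  # degrade di to mono when no pairs exist
        is_di = np.zeros_like(is_di)

    chrom_lookup: list[str] = []
    if is_mono.any() or is_di.any():
        chrom_lookup = chroms_with_dyads
    if is_mono.any():
        idx = rng.integers(0, len(all_dyads), size=int(is_mono.sum()))
        d = all_dyads[idx]
        start[is_mono] = d - lengths[is_mono] // 2
        end[is_mono] = start[is_mono] + lengths[is_mono]
        chrom_idx[is_mono] = dyad_chrom_idx[idx]
        chrom_arrays[0] = chroms_with_dyads
    if is_di.any():
        idx = rng.integers(0, len(pairs_l), size=int(is_di.sum()))
        d1, d2 = pairs_l[idx], pairs_r[idx]
        span = (d2 - d1) + lengths[is_di]
        centre = (d1 + d2) // 2
        start[is_di] = centre - span // 2
        end[is_di] = start[is_di] + span
        chrom_idx[is_di] = pair_chrom_idx[idx]
    if is_free.any():
        lens = np.array([sizes[c] for c in chrom_names], dtype=float)
        # free fragments live on the genome's chromosome list, so unify the
        # chromosome lookup before assigning indices
        offset = len(chrom_lookup)
        chrom_lookup = chrom_lookup + chrom_names
        ci = rng.choice(len(chrom_names), size=int(is_free.sum()), p=lens / lens.sum())
        max_start = np.maximum(
            np.array([sizes[c] for c in chrom_names], dtype=np.int64)[ci]
            - lengths[is_free],
            1,
        )
        start[is_free] = (rng.random(int(is_free.sum())) * max_start).astype(np.int64)
        end[is_free] = start[is_free] + lengths[is_free]
        chrom_idx[is_free] = ci + offset
    else:
        chrom_lookup = chrom_lookup or chroms_with_dyads

    chrom_sizes = np.array([sizes[chrom_lookup[k]] for k in range(len(chrom_lookup))])
    start = np.maximum(start, 0)
    end = np.minimum(end, chrom_sizes[chrom_idx])
    end = np.maximum(end, start + 1)
    out_chrom = [chrom_lookup[k] for k in chrom_idx]

    return FragmentSet.from_arrays(
        out_chrom, start, end, strand=".", label=label, sample_id=sample_id
    )


def gen_lane_trace(
    bands: list[tuple[float, float, float]],
    ladder: list[float],
    noise_sd: float,
    trace_len: int = 1000,
    seed: int = 0,
) -> LaneTrace:
    """Synthetic densitometry trace: Gaussian bands in log-size coordinate.

    ``bands`` are (size bp, area, width_sd bp) triples. The migration
    coordinate is linear in log10(size), with the extreme ladder (or band)
    sizes mapped to 5% / 95% of the trace so everything is on-scale. Each band
    is a Gaussian whose position-space integral equals the requested area;
    Normal noise is added and the trace floored at zero. Ladder peak positions
    are recorded on the returned trace. An empty band list gives a flat noise
    trace.
    """
    for size, area, _ in bands:
        if size <= 0:
            raise InputError("band sizes must be positive")
        if area < 0:
            raise InputError("band areas must be >= 0")
    rng = _rng(seed, _STREAM_LANE)
    ref_sizes = list(ladder) if ladder else [s for s, _, _ in bands]
    if not ref_sizes:
        ref_sizes = [50.0, 1000.0]
    smin, smax = min(ref_sizes), max(ref_sizes)
    if smax == smin:
        smax = smin * 2
    # larger fragments migrate less: position increases as size decreases
    top, bottom = 0.05 * trace_len, 0.95 * trace_len
    scale = (bottom - top) / (np.log10(smax) - np.log10(smin))

    def pos_of(size: float | np.ndarray) -> np.ndarray:
        return top + (np.log10(smax) - np.log10(np.asarray(size, dtype=float))) * scale

    positions = np.arange(trace_len, dtype=float)
    intensities = np.zeros(trace_len, dtype=float)
    for size, area, width_sd in bands:
        centre = pos_of(size)
        sd_pos = scale * width_sd / (size * np.log(10))
        sd_pos = max(float(sd_pos), 0.5)
        intensities += (
            area
            / (sd_pos * np.sqrt(2 * np.pi))
            * np.exp(-0.5 * ((positions - centre) / sd_pos) ** 2)
        )
    if noise_sd > 0:
        intensities += rng.normal(0.0, noise_sd, size=trace_len)
    intensities = np.clip(intensities, 0.0, None)
    ladder_points = [(float(pos_of(s)), float(s)) for s in ladder]
    return LaneTrace(positions=positions, intensities=intensities, ladder=ladder_points)


def gen_silac_table(
    true_ratio_per_protein: dict[str, float],
    n_peptides_per_protein: int,
    noise_cv: float,
    seed: int,
    base_intensity: float = 1e6,
    intensity_log_sd: float = 1.0,
) -> list[PeptideRecord]:
    """Heavy/light peptide intensities lognormal around known true ratios.

    Peptide light intensities are lognormal around ``base_intensity``; the
    heavy intensity is light * true_ratio * a lognormal multiplicative noise
    with coefficient of variation ``noise_cv`` (exact ratios at cv 0).
    """
    if any(r <= 0 for r in true_ratio_per_protein.values()):
        raise InputError("true ratios must be positive")
    if noise_cv < 0:
        raise InputError("noise_cv must be >= 0")
    rng = _rng(seed, _STREAM_SILAC)
    sigma = np.sqrt(np.log1p(noise_cv**2))
    records: list[PeptideRecord] = []
    for pid in sorted(true_ratio_per_protein):
        ratio = true_ratio_per_protein[pid]
        light = base_intensity * np.exp(
            rng.normal(0.0, intensity_log_sd, size=n_peptides_per_protein)
        )
        if sigma > 0:
            # mean-one lognormal noise on the ratio
            noise = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=n_peptides_per_protein))
        else:
            noise = np.ones(n_peptides_per_protein)
        heavy = light * ratio * noise
        records.extend(
            PeptideRecord(
                protein_id=pid,
                peptide_id=f"{pid}_pep{k}",
                heavy_intensity=float(heavy[k]),
                light_intensity=float(light[k]),
            )
            for k in range(n_peptides_per_protein)
        )
    return records
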