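"""Stochastic simulator of lagging-strand synthesis coupled to nucleosome
deposition and PCNA unloading.

The model
---------
A replication fork moves along a strand of ``strand_length`` bp at
``fork_speed`` (time is normalized so the default speed is 1 bp per time
unit). Primers are laid at renewal spacings ``primer_spacing_min +
Exponential(primer_spacing_mean - primer_spacing_min)``. Each Okazaki
fragment is synthesized from its primer back toward previously replicated
DNA: it closes the gap to the preceding primer and then nick-translates,
displacing the 5' end of the preceding fragment, until its polymerase runs
into the edge of a nucleosome already deposited on that DNA - the nucleosome
is the barrier that stimulates polymerase disengagement - or until a cap of
``max_displacement`` bp of strand displacement is reached. The stop position
becomes a ligation junction; consecutive junctions delimit the final,
ligated fragments, so fragment length is set by the first nucleosome barrier
on the preceding fragment.

One PCNA clamp is loaded per primer and modeled as a point obstacle at its
load position; clamp sliding is not modeled, so the obstacle stays where the
clamp was loaded, at a position that is random relative to the nucleosome
lattice emerging behind the fork. After its fragment's ligation the clamp is
unloaded with exponential waiting time at rate ``k_elg1 + k_spont``: the
Elg1-RLC pathway (requires ligation) plus spontaneous dissociation (the
trimer-instability pathway).

Nucleosomes are deposited behind the fork at rate ``deposition_rate``, each
at the leftmost position at least one repeat (footprint + linker) beyond the
last dyad - with Normal(0, ``deposition_jitter_sd``) positional noise -
whose footprint, widened by ``pcna_block_halfwidth`` on each side, is free
of resident PCNA (a nucleosome cannot be assembled over a clamp); blocked
positions are skipped rightward past the clamp. In the wild type clamps
unload before the deposition frontier reaches them and the array is an
undisturbed ~repeat lattice; under delayed unloading resident clamps force
skips that leave nucleosome-free gaps, disorder the array and remove the
barriers that keep fragments short - the fragment lengthening and MNase
hypersensitivity of delayed-unloading conditions are emergent, not
parameterized.
"""

from __future__ import annotations

import bisect
import heapq
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy.stats import ks_2samp

from .errors import InputError


@dataclass(frozen=True)
class SimParams:
    """Parameters of the lagging-strand model.

    Rates are per time unit; with the default ``fork_speed`` of 1 bp/unit
    they read as events per bp of fork travel.
    """

    strand_length: int = 200_000
    fork_speed: float = 1.0
    primer_spacing_mean: float = 150.0
    primer_spacing_min: float = 50.0
    nucleosome_footprint: int = 147
    linker_length: int = 33
    deposition_rate: float = 2.0
    deposition_jitter_sd: float = 10.0
    k_elg1: float = 1.0
    k_spont: float = 0.001
    pcna_block_halfwidth: float = 15.0
    max_displacement: float = 1000.0
    seed: int = 0

    @property
    def repeat(self) -> int:
        return self.nucleosome_footprint + self.linker_length

    def validate(self) -> None:
        if self.strand_length < 0:
            raise InputError("strand_length must be >= 0")
        if self.fork_speed <= 0:
            raise InputError("fork_speed must be positive")
        if self.primer_spacing_min <= 0:
            raise InputError("primer_spacing_min must be positive")
        if self.primer_spacing_mean < self.primer_spacing_min:
            raise InputError("primer_spacing_mean must be >= primer_spacing_min")
        if self.linker_length < 0:
            raise InputError("repeat must be >= footprint (linker >= 0)")
        for name in ("deposition_rate", "k_elg1", "k_spont"):
            if getattr(self, name) < 0:
                raise InputError(f"{name} must be >= 0")
        if self.deposition_jitter_sd < 0:
            raise InputError("deposition_jitter_sd must be >= 0")
        if self.max_displacement <= 0:
            raise InputError("max_displacement must be positive")


@dataclass(frozen=True)
class Fragment:
    start: float
    end: float
    ligation_time: float

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class PcnaEvent:
    """One clamp: loaded at its fragment's primer, unloaded after ligation
    or still resident at the end of the run."""

    position: float
    load_time: float
    unload_time: float  # inf if still resident at the end
    fate: str  # "unloaded" | "retained"


@dataclass
class SimResult:
    fragments: list[Fragment]
    dyad_positions: np.ndarray
    dyad_times: np.ndarray
    pcna_events: list[PcnaEvent]
    params: SimParams
    end_time: float

    def fragment_lengths(self) -> np.ndarray:
        return np.array([f.length for f in self.fragments], dtype=float)


@dataclass
class LengthDistribution:
    """Histogram of fragment lengths over [0, max] with fixed-width bins."""

    bin_width: float
    bin_counts: np.ndarray
    n: int
    modes: list[float] = field(default_factory=list)

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(len(self.bin_counts)) + 0.5) * self.bin_width


@dataclass
class MnaseReadout:
    """Mass fractions of an in-silico MNase digest of the nascent strand."""

    mono_fraction: float
    di_fraction: float
    sub_fraction: float
    higher_fraction: float
    total_mass: float
    n_fragments: int


class _PcnaPool:
    """Resident clamps indexed by position (sorted) and by unload time (heap)."""

    def __init__(self) -> None:
        self.by_pos: list[tuple[float, int]] = []
        self.heap: list[tuple[float, int]] = []
        self.alive: dict[int, tuple[float, float]] = {}  # id -> (pos, unload)
        self.events: list[PcnaEvent] = []
        self._next_id = 0

    def load(self, pos: float, load_time: float, unload_time: float) -> int:
        pid = self._next_id
        self._next_id += 1
        self.alive[pid] = (pos, unload_time)
        bisect.insort(self.by_pos, (pos, pid))
        if math.isfinite(unload_time):
            heapq.heappush(self.heap, (unload_time, pid))
        self.events.append(PcnaEvent(pos, load_time, unload_time, "retained"))
        return pid

    def _drop(self, pid: int, unload_time: float, fate: str) -> None:
        pos, _ = self.alive.pop(pid)
        i = bisect.bisect_left(self.by_pos, (pos, pid))
        del self.by_pos[i]
        ev = self.events[pid]
        self.events[pid] = PcnaEvent(ev.position, ev.load_time, unload_time, fate)

    def purge(self, now: float) -> None:
        while self.heap and self.heap[0][0] <= now:
            t, pid = heapq.heappop(self.heap)
            if pid in self.alive and self.alive[pid][1] == t:
                self._drop(pid, t, "unloaded")

    def next_unload(self) -> float:
        while self.heap and self.heap[0][1] not in self.alive:
            heapq.heappop(self.heap)
        return self.heap[0][0] if self.heap else math.inf

    def slide_free(self, p: float, halfwidth: float) -> float:
        """Smallest q >= p with no resident clamp in [q - hw, q + hw]."""
        while True:
            i = bisect.bisect_left(self.by_pos, (p - halfwidth, -1))
            blocker = None
            while i < len(self.by_pos) and self.by_pos[i][0] <= p + halfwidth:
                blocker = self.by_pos[i][0]
                i += 1
            if blocker is None:
                return p
            p = math.floor(blocker + halfwidth) + 1.0


def simulate_lagging_strand(params: SimParams) -> SimResult:
    """Run the event loop for one strand. Deterministic given ``params.seed``."""
    params.validate()
    L = float(params.strand_length)
    if L <= 0:
        return SimResult([], np.array([]), np.array([]), [], params, 0.0)

    rng = np.random.default_rng(params.seed)
    speed = params.fork_speed
    repeat = float(params.repeat)
    footprint = params.nucleosome_footprint
    half_left = footprint // 2
    half_right = footprint - half_left
    hw = params.pcna_block_halfwidth
    rate = params.deposition_rate
    jitter = params.deposition_jitter_sd
    k_total = params.k_elg1 + params.k_spont

    # primer positions along the strand
    scale = params.primer_spacing_mean - params.primer_spacing_min
    primers: list[float] = []
    x = 0.0
    while True:
        x += params.primer_spacing_min + (rng.exponential(scale) if scale > 0 else 0.0)
        if x >= L:
            break
        primers.append(x)

    dyad_pos: list[float] = []
    dyad_time: list[float] = []
    last_dyad: float | None = None
    pool = _PcnaPool()
    frontier = 0.0
    next_depo = rng.exponential(1.0 / rate) if rate > 0 else math.inf

    # a clamp blocks any dyad whose footprint, widened by hw, would cover it
    exclusion = half_left + hw

    def attempt_deposit(tau: float) -> bool:
        nonlocal last_dyad, next_depo
        pool.purge(tau)
        base = (last_dyad + repeat) if last_dyad is not None else float(half_left)
        p = base + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        p = round(p)
        min_allowed = (last_dyad + footprint) if last_dyad is not None else float(half_left)
        p = max(p, min_allowed)
        p = pool.slide_free(p, exclusion)
        if p + half_right > frontier:
            return False
        dyad_pos.append(p)
        dyad_time.append(tau)
        last_dyad = p
        return True

    def advance_deposition(t_end: float) -> None:
        nonlocal next_depo
        while next_depo <= t_end:
            tau = next_depo
            if attempt_deposit(tau):
                next_depo = tau + rng.exponential(1.0 / rate)
            else:
                # nothing can change until a clamp unloads or the frontier
                # advances; Poisson memorylessness makes the jump exact
                t_change = min(pool.next_unload(), t_end)
                next_depo = t_change + rng.exponential(1.0 / rate)
                if t_change >= t_end:
                    return

    junction_pos: list[float] = []
    junction_time: list[float] = []

    def terminate(nick: float, t_now: float, clamp_pos: float | None) -> None:
        barrier = (dyad_pos[-1] + half_right) if dyad_pos else -math.inf
        stop = max(barrier, nick - params.max_displacement, 0.0)
        # a stop at/below the previous junction means the preceding fragment
        # was fully displaced and re-synthesized: merge (drop its junction)
        while junction_pos and junction_pos[-1] >= stop - 1e-9:
            junction_pos.pop()
            junction_time.pop()
        junction_pos.append(stop)
        junction_time.append(t_now)
        if clamp_pos is not None:
            # ligation-gated unloading: the clock starts now, at ligation
            unload = t_now + (rng.exponential(1.0 / k_total) if k_total > 0 else math.inf)
            pool.load(clamp_pos, t_now, unload)

    prev_x = 0.0
    for i, px in enumerate(primers):
        t_i = px / speed
        advance_deposition(t_i)
        pool.purge(t_i)
        if i == 0:
            # first fragment runs back to the strand start (the leading-strand
            # junction at the origin); no nick translation, no cap
            terminate(0.0, t_i, clamp_pos=px)
        else:
            terminate(prev_x, t_i, clamp_pos=px)
        frontier = px
        prev_x = px

    # the fork reaches the strand end: the final stretch terminates like any
    # other fragment, against the last chromatinized edge (no primer of its
    # own, e.g. it meets a converging fork), so no clamp is loaded
    t_end = L / speed
    advance_deposition(t_end)
    pool.purge(t_end)
    if primers:
        terminate(prev_x, t_end, clamp_pos=None)
    else:
        junction_pos.append(0.0)
        junction_time.append(t_end)
    frontier = L

    bounds = junction_pos + [L]
    fragments = [
        Fragment(bounds[k], bounds[k + 1], junction_time[k])
        for k in range(len(junction_pos))
        if bounds[k + 1] > bounds[k]
    ]
    return SimResult(
        fragments=fragments,
        dyad_positions=np.array(dyad_pos, dtype=float),
        dyad_times=np.array(dyad_time, dtype=float),
        pcna_events=list(pool.events),
        params=params,
        end_time=t_end,
    )


def length_distribution(lengths, bin_width: float) -> LengthDistribution:
    """Histogram of fragment lengths over [0, max] with ``bin_width`` bins."""
    if bin_width <= 0:
        raise InputError("bin_width must be positive")
    lengths = np.asarray(lengths, dtype=float)
    n = len(lengths)
    if n == 0:
        return LengthDistribution(bin_width, np.zeros(0, dtype=np.int64), 0)
    n_bins = int(math.ceil((lengths.max() + 1e-9) / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts, _ = np.histogram(lengths, bins=edges)
    return LengthDistribution(bin_width, counts.astype(np.int64), n)


def find_modes(
    dist: LengthDistribution,
    min_separation: float = 100.0,
    min_fraction: float = 0.01,
    smooth_bins: int = 3,
) -> list[float]:
    """Histogram modes: local maxima >= ``min_separation`` apart, each holding
    at least ``min_fraction`` of the mass in its (raw) bin.

    The histogram is lightly smoothed (``smooth_bins`` moving average) before
    peak finding; ties break toward smaller size. Modes are bin centers,
    sorted ascending.
    """
    if min_separation < dist.bin_width:
        raise InputError("min_separation must be >= bin_width")
    counts = dist.bin_counts.astype(float)
    if dist.n == 0 or len(counts) == 0:
        return []
    w = max(1, int(smooth_bins) | 1)
    kernel = np.ones(w)
    sm = np.convolve(counts, kernel, mode="same") / np.convolve(
        np.ones_like(counts), kernel, mode="same"
    )
    # plateau-aware peak search: a maximal run of equal smoothed values is a
    # peak when it dominates both flanks (the histogram is zero outside its
    # range); the peak's bin is the run's highest raw bin, ties to the left
    candidates: list[int] = []
    i = 0
    while i < len(sm):
        j = i
        while j + 1 < len(sm) and sm[j + 1] == sm[i]:
            j += 1
        left = sm[i - 1] if i > 0 else 0.0
        right = sm[j + 1] if j + 1 < len(sm) else 0.0
        if sm[i] > left and sm[i] > right:
            candidates.append(i + int(np.argmax(counts[i : j + 1])))
        i = j + 1
    # greedy by height, ties toward smaller size
    candidates.sort(key=lambda k: (-sm[k], k))
    centers = dist.bin_centers
    accepted: list[int] = []
    for i in candidates:
        if all(abs(centers[i] - centers[j]) >= min_separation for j in accepted):
            accepted.append(i)
    modes = [
        float(centers[i]) for i in accepted if counts[i] >= min_fraction * dist.n
    ]
    return sorted(modes)


def mnase_readout(
    result: SimResult,
    sample_time: float,
    cut_coeff: float = 0.01,
    seed: int | None = None,
) -> MnaseReadout:
    """In-silico MNase digest of the nascent strand at ``sample_time``.

    Nucleosomes deposited by the sample time protect their footprint; each
    naked stretch (linker or gap) receives a cut with probability
    1 - exp(-cut_coeff * length), at a uniform point. The resulting protected
    fragments are classified by nucleosome count (0 / 1 / 2 / more) and their
    bp mass fractions of the synthesized DNA returned.
    """
    if cut_coeff <= 0:
        raise InputError("cut_coeff must be positive")
    params = result.params
    footprint = params.nucleosome_footprint
    half_left = footprint // 2
    half_right = footprint - half_left
    synthesized = min(sample_time * params.fork_speed, float(params.strand_length))
    if synthesized <= 0:
        return MnaseReadout(0.0, 0.0, 0.0, 0.0, 0.0, 0)

    sel = result.dyad_times <= sample_time
    dyads = np.sort(result.dyad_positions[sel])
    starts = np.clip(dyads - half_left, 0.0, synthesized)
    ends = np.clip(dyads + half_right, 0.0, synthesized)
    keep = ends > starts
    starts, ends = starts[keep], ends[keep]

    rng = np.random.default_rng(
        (params.seed + 104_729) if seed is None else seed
    )
    # walk naked stretches, sampling cut points
    cuts: list[float] = []
    prev_end = 0.0
    stretch_bounds = list(zip(starts, ends)) + [(synthesized, synthesized)]
    for s, e in stretch_bounds:
        gap = s - prev_end
        if gap > 0 and rng.random() < -math.expm1(-cut_coeff * gap):
            cuts.append(prev_end + rng.random() * gap)
        prev_end = max(prev_end, e)

    boundaries = [0.0] + cuts + [synthesized]
    masses = {0: 0.0, 1: 0.0, 2: 0.0, 3: 0.0}
    n_frag = 0
    for k in range(len(boundaries) - 1):
        lo, hi = boundaries[k], boundaries[k + 1]
        if hi <= lo:
            continue
        n_frag += 1
        # count nucleosomes whose dyad lies in [lo, hi)
        n_nuc = int(np.searchsorted(dyads, hi) - np.searchsorted(dyads, lo))
        masses[min(n_nuc, 3)] += hi - lo
    total = synthesized
    return MnaseReadout(
        mono_fraction=masses[1] / total,
        di_fraction=masses[2] / total,
        sub_fraction=masses[0] / total,
        higher_fraction=masses[3] / total,
        total_mass=total,
        n_fragments=n_frag,
    )


@dataclass
class ConditionComparison:
    """Pooled and per-replicate comparison of two simulated conditions."""

    mean_length_a: float
    mean_length_b: float
    mean_length_diff: float
    modes_a: list[float]
    modes_b: list[float]
    mono_fractions_a: list[float]
    mono_fractions_b: list[float]
    mono_fold_change: float
    ks_distance: float
    n_fragments_a: int
    n_fragments_b: int


def replicate_seeds(base_seed: int, n_reps: int) -> list[int]:
    """Replicate seeds are base seed + replicate index."""
    return [base_seed + r for r in range(n_reps)]


def run_replicates(params: SimParams, n_reps: int) -> list[SimResult]:
    return [
        simulate_lagging_strand(replace(params, seed=s))
        for s in replicate_seeds(params.seed, n_reps)
    ]


def compare_conditions(
    params_a: SimParams,
    params_b: SimParams,
    n_reps: int,
    sample_frac: float = 0.6,
    cut_coeff: float = 0.01,
    bin_width: float = 5.0,
    min_separation: float = 100.0,
    min_fraction: float = 0.01,
) -> ConditionComparison:
    """Replicate both conditions and summarize their differences.

    Reports pooled mean-length difference, histogram modes per condition,
    the fold change of the mean mono-nucleosomal MNase fraction (a over b,
    sampled at ``sample_frac`` of strand completion) and the
    Kolmogorov-Smirnov distance between the pooled length distributions.
    """
    if n_reps < 1:
        raise InputError("n_reps must be >= 1")

    def run(params: SimParams):
        lengths: list[np.ndarray] = []
        monos: list[float] = []
        t_sample = sample_frac * params.strand_length / params.fork_speed
        for res in run_replicates(params, n_reps):
            lengths.append(res.fragment_lengths())
            monos.append(mnase_readout(res, t_sample, cut_coeff).mono_fraction)
        return np.concatenate(lengths), monos

    len_a, mono_a = run(params_a)
    len_b, mono_b = run(params_b)
    dist_a = length_distribution(len_a, bin_width)
    dist_b = length_distribution(len_b, bin_width)
    mean_b_mono = float(np.mean(mono_b))
    return ConditionComparison(
        mean_length_a=float(len_a.mean()),
        mean_length_b=float(len_b.mean()),
        mean_length_diff=float(len_a.mean() - len_b.mean()),
        modes_a=find_modes(dist_a, min_separation, min_fraction),
        modes_b=find_modes(dist_b, min_separation, min_fraction),
        mono_fractions_a=mono_a,
        mono_fractions_b=mono_b,
        mono_fold_change=float(np.mean(mono_a)) / mean_b_mono if mean_b_mono > 0 else math.inf,
        ks_distance=float(ks_2samp(len_a, len_b).statistic),
        n_fragments_a=int(len(len_a)),
        n_fragments_b=int(len(len_b)),
    )


PRESET_NAMES = ("wt", "elg1d", "pol30-r14e", "pol30-d150e", "cac")


def get_preset(name: str) -> SimParams:
    """Load a named condition preset shipped with the package.

    ``wt``: fast ligation-coupled unloading. ``elg1d``: no Elg1 pathway,
    near-zero spontaneous unloading (clamp retention). ``pol30-r14e`` /
    ``pol30-d150e``: no Elg1 pathway but disassembly-prone clamps
    (spontaneous unloading rescues retention). ``cac``: reduced deposition
    rate (chromatin-assembly-factor deficient).
    """
    key = name.lower().replace("_", "-")
    if key not in PRESET_NAMES:
        raise InputError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    fname = key.replace("-", "_") + ".yaml"
    text = resources.files("replichrom.presets").joinpath(fname).read_text()
    return SimParams(**yaml.safe_load(text))
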