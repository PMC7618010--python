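"""Synthetic cohort generator for the reversion-monitoring pipeline.

Generates every input the downstream stages consume — a coding-frame locus,
pathogenic frameshift/stop-gain lesions, frame-restoring secondary events with
microhomology-biased deletion junctions, targeted-panel reads (~4,600x raw
depth at the variant site), longitudinal allele-frequency trajectories,
survival times whose hazard depends on the time-varying reversion count, and
binned BAF/logR tracks for mixtures of homozygously deleted and copy-retaining
tumor subclones. Truth labels are retained end to end so sensitivity and
specificity of the pipeline are exactly computable. Every generator is a pure
function of its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reversion import (
    STOP_CODONS,
    LocusReference,
    PathogenicVariant,
    Read,
    SecondaryEvent,
    apply_events,
    has_premature_stop,
    left_align,
    microhomology,
    net_frame_change,
    spans_pathogenic,
)
from . import cnclone

DAYS_PER_MONTH = 30.44  # time-unit convention used throughout the package

__all__ = [
    "DAYS_PER_MONTH",
    "TrajectoryParams",
    "SurvivalSimParams",
    "CNSimParams",
    "LocusScenario",
    "gen_locus",
    "gen_pathogenic",
    "gen_reversion_events",
    "sim_reads",
    "sim_longitudinal",
    "sim_survival",
    "sim_baf_logr",
]


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryParams:
    """Clone-dynamics parameters for one patient's longitudinal simulation.

    The pathogenic clone declines exponentially to a nadir (drug response) and
    regrows logistically; each reversion clone grows logistically from its
    birth time. Allele fractions; rates are per day.
    """

    pathogenic_af0: float = 0.30
    response_nadir_day: float = 56.0
    regrowth_rate: float = 0.04
    reversion_birth_times: tuple[float, ...] = (84.0, 112.0)
    reversion_growth_rates: tuple[float, ...] = (0.06, 0.06)
    detection_depth: int = 4600
    nadir_fraction: float = 0.01      # nadir AF as a fraction of pathogenic_af0
    reversion_af_cap: float = 0.20    # logistic carrying capacity per reversion clone
    pathogenic_af_cap: float = 0.50

    def __post_init__(self) -> None:
        if not (0.0 <= self.pathogenic_af0 <= 1.0):
            raise ValueError("pathogenic_af0 must be in [0,1]")
        if self.detection_depth <= 0:
            raise ValueError("detection_depth must be positive")
        for r in (self.regrowth_rate, *self.reversion_growth_rates):
            if not math.isfinite(r):
                raise ValueError("rates must be finite")
        if len(self.reversion_birth_times) != len(self.reversion_growth_rates):
            raise ValueError("birth times and growth rates must align")


@dataclass(frozen=True)
class SurvivalSimParams:
    """Hazard model for survival simulation: lambda(t) = h0 * exp(beta * count(t))."""

    baseline_hazard: float = 0.10     # events / month
    log_hr_per_reversion: float = math.log(2.0)
    censor_rate: float = 0.0          # events / month, independent censoring
    n_patients: int = 19
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_hazard < 0 or self.censor_rate < 0:
            raise ValueError("hazards must be >= 0")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")


@dataclass(frozen=True)
class CNSimParams:
    """Locus copy-number mixture parameters for BAF/logR track simulation.

    ``homdel_fraction`` is the tumor-cell fraction in the homozygously deleted
    state (0,0) at end of treatment; the baseline track is simulated as a
    clonal homozygous deletion. Noise SDs default to values matching ~60x
    whole-genome coverage binned at the locus scale.
    """

    purity: float = 0.5
    ploidy: float = 2.0
    homdel_fraction: float = 0.5
    background_state: tuple[int, int] = (1, 1)
    n_bins: int = 300
    baf_noise_sd: float = 0.03
    logr_noise_sd: float = 0.15
    seed: int = 0
    contig: str = "chr13"
    bin_start: int = 32_800_000
    bin_size: int = 10_000

    def __post_init__(self) -> None:
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0,1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")
        if not (0.0 <= self.homdel_fraction <= 1.0):
            raise ValueError("homdel_fraction must be in [0,1]")
        na, nb = self.background_state
        if not (na >= nb >= 0):
            raise ValueError("background state must satisfy nA >= nB >= 0")
        if self.n_bins < 2:
            raise ValueError("need at least 2 bins")


@dataclass(frozen=True)
class LocusScenario:
    """A locus, its pathogenic lesion and the true reversion events."""

    locus: LocusReference
    pathogenic: PathogenicVariant
    reversions: tuple[tuple[SecondaryEvent, ...], ...]


# ---------------------------------------------------------------------------
# Locus and lesion generation
# ---------------------------------------------------------------------------

def gen_locus(seed: int, length: int, gc: float = 0.5, name: str = "locus") -> LocusReference:
    """Random coding-frame locus: no stop codon in frame 0.

    Codons are drawn base-by-base with P(G) = P(C) = gc/2 and redrawn when a
    stop codon arises, so the frame-0 translation is open across the whole
    locus (as for a CDS-centred window). Deterministic for a fixed seed.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not (0.0 < gc < 1.0):
        raise ValueError("gc must be in (0,1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    bases = np.array(list("ACGT"))
    n_codons = length // 3 + 1
    out: list[str] = []
    for _ in range(n_codons):
        while True:
            codon = "".join(rng.choice(bases, size=3, p=p))
            if codon not in STOP_CODONS:
                out.append(codon)
                break
    return LocusReference(name=name, sequence="".join(out)[:length], offset=1)


def gen_pathogenic(
    locus: LocusReference,
    klass: str = "frameshift",
    pos: int | None = None,
    seed: int = 0,
    gene: str = "GENE",
    net_len: int = -1,
    origin: str = "somatic",
) -> PathogenicVariant:
    """A pathogenic lesion near the middle of the locus.

    Frameshift: an anchored deletion/insertion of ``net_len`` (not 0 mod 3).
    Stop-gain: the codon nearest ``pos`` replaced by a single-nucleotide-change
    stop codon.
    """
    rng = np.random.default_rng(seed)
    if pos is None:
        pos = locus.offset + len(locus) // 2
    if klass == "frameshift":
        if net_len % 3 == 0:
            raise ValueError("frameshift net length must not be 0 mod 3")
        if net_len < 0:
            ref = locus.slice(pos, pos - net_len)
            alt = ref[0]
        else:
            ref = locus.base(pos)
            alt = ref + "".join(rng.choice(list("ACGT"), size=net_len))
        ev = left_align(SecondaryEvent(pos, ref, alt), locus)
        return PathogenicVariant(gene, locus.name, ev.pos, ev.ref, ev.alt, "frameshift", origin)
    if klass == "stop_gain":
        codon_start = locus.offset + ((pos - locus.offset) // 3) * 3
        ref_codon = locus.slice(codon_start, codon_start + 2)
        # single-nucleotide changes of the reference codon that give a stop
        options = []
        for stop in sorted(STOP_CODONS):
            diff = sum(a != b for a, b in zip(ref_codon, stop))
            if diff == 1:
                options.append(stop)
        if not options:
            # fall back to the nearest codon (scan outward) with a 1-nt stop change
            for step in range(1, len(locus) // 3):
                for direction in (-1, 1):
                    cs = codon_start + 3 * step * direction
                    if cs < locus.offset or cs + 2 > locus.offset + len(locus) - 1:
                        continue
                    rc = locus.slice(cs, cs + 2)
                    opts = [s for s in sorted(STOP_CODONS)
                            if sum(a != b for a, b in zip(rc, s)) == 1]
                    if opts:
                        return PathogenicVariant(
                            gene, locus.name, cs, rc,
                            opts[int(rng.integers(len(opts)))], "stop_gain", origin,
                        )
            raise ValueError("no stop-gain-compatible codon found")
        alt = options[int(rng.integers(len(options)))]
        return PathogenicVariant(gene, locus.name, codon_start, ref_codon, alt, "stop_gain", origin)
    raise ValueError(f"unknown pathogenic class {klass!r}")


# ---------------------------------------------------------------------------
# Reversion event generation
# ---------------------------------------------------------------------------

def _frame_ok(
    locus: LocusReference, pathogenic: PathogenicVariant, events: tuple[SecondaryEvent, ...]
) -> bool:
    """Events restore frame with the pathogenic lesion and leave the ORF open."""
    try:
        if net_frame_change(pathogenic, events) != 0:
            return False
    except ValueError:
        return False
    if any(spans_pathogenic(e, pathogenic) for e in events):
        applied = sorted(events, key=lambda e: e.pos)
    else:
        applied = sorted((*events, pathogenic.as_event()), key=lambda e: e.pos)
    try:
        hap = apply_events(locus, applied)
    except ValueError:
        return False
    first_pos = min(e.pos for e in applied)
    shift = 0
    for e in applied:
        if e.ref_span[1] < first_pos:
            shift += e.net_len
    return not has_premature_stop(hap, first_pos - locus.offset + shift)


def _clear_of_pathogenic(ev: SecondaryEvent, pathogenic: PathogenicVariant, gap: int = 8) -> bool:
    """Event keeps >= ``gap`` matching bases from the pathogenic footprint.

    Secondary events flush against the pathogenic indel can collapse with it
    into a single substitution-like difference on the haplotype, which no
    longer reads as an indel pair; real reversions separated by a short
    matching tract are kept.
    """
    p_lo, p_hi = pathogenic.pos, pathogenic.pos + len(pathogenic.ref) - 1
    e_lo, e_hi = ev.ref_span
    return e_lo - p_hi > gap or p_lo - e_hi > gap


def _deletion_candidates(
    locus: LocusReference,
    pathogenic: PathogenicVariant,
    max_mh: int,
    max_dist: int = 60,
    max_del: int = 24,
) -> tuple[list[SecondaryEvent], list[SecondaryEvent]]:
    """Frame-restoring deletions near the pathogenic site, split by junction MH.

    Returns (mh_pool, no_mh_pool): deletions whose left-aligned junction carries
    2..max_mh nt of microhomology versus <2 nt.
    """
    # deletion of d bases has net -d; restoring needs (net - d) % 3 == 0
    need = pathogenic.net_len % 3
    mh_pool: list[SecondaryEvent] = []
    no_mh_pool: list[SecondaryEvent] = []
    seen: set[tuple] = set()
    lo = max(locus.offset + 1, pathogenic.pos - max_dist)
    hi = min(locus.offset + len(locus) - 1 - max_del, pathogenic.pos + max_dist)
    for start in range(lo, hi + 1):
        for d in range(2, max_del + 1):
            if d % 3 != need:
                continue
            anchor_pos = start - 1
            ref = locus.slice(anchor_pos, anchor_pos + d)
            ev = left_align(SecondaryEvent(anchor_pos, ref, ref[0]), locus)
            if ev.key() in seen:
                continue
            seen.add(ev.key())
            if spans_pathogenic(ev, pathogenic):
                continue
            if not _clear_of_pathogenic(ev, pathogenic):
                continue
            if not _frame_ok(locus, pathogenic, (ev,)):
                continue
            mh, _ = microhomology(ev, locus)
            if 2 <= mh <= max_mh:
                mh_pool.append(ev)
            elif mh < 2:
                no_mh_pool.append(ev)
    return mh_pool, no_mh_pool


def gen_reversion_events(
    pathogenic: PathogenicVariant,
    n_events: int,
    mh_bias: float,
    max_mh: int,
    seed: int,
    ref_seq: LocusReference,
    class_mix: tuple[float, float, float] = (0.72, 0.09, 0.19),
) -> list[tuple[SecondaryEvent, ...]]:
    """True reversion events around ``pathogenic``, as event tuples.

    For frameshift lesions the class mix (deletion, insertion, complex)
    defaults to the proportions observed in panel cohorts of this kind
    (82:10:22). A fraction ``mh_bias`` of deletions is drawn from junctions
    with 2..``max_mh`` nt microhomology (MMEJ-like scars); the rest from
    junctions without. Every returned tuple restores the reading frame in
    combination with the pathogenic lesion and keeps the downstream ORF open.
    For stop-gain lesions, events are single-nucleotide codon substitutions to
    non-stop, non-reference codons.
    """
    if pathogenic.klass not in ("frameshift", "stop_gain"):
        raise ValueError("pathogenic lesion must be frameshift or stop-gain")
    rng = np.random.default_rng(seed)

    if pathogenic.klass == "stop_gain":
        options = []
        stop = pathogenic.alt
        for i in range(3):
            for b in "ACGT":
                if b == stop[i]:
                    continue
                codon = stop[:i] + b + stop[i + 1 :]
                if codon in STOP_CODONS or codon == pathogenic.ref:
                    continue
                options.append(
                    SecondaryEvent(pathogenic.pos, pathogenic.ref, codon)
                )
        if n_events > len(options):
            raise ValueError(
                f"only {len(options)} distinct stop-gain reversions exist"
            )
        idx = rng.choice(len(options), size=n_events, replace=False)
        return [(options[i],) for i in sorted(idx)]

    mh_pool, no_mh_pool = _deletion_candidates(ref_seq, pathogenic, max_mh)
    rng.shuffle(mh_pool)
    rng.shuffle(no_mh_pool)

    out: list[tuple[SecondaryEvent, ...]] = []
    used: set[tuple] = set()

    def take_deletion() -> tuple[SecondaryEvent, ...] | None:
        pools = (
            (mh_pool, no_mh_pool) if rng.random() < mh_bias else (no_mh_pool, mh_pool)
        )
        for pool in pools:
            while pool:
                ev = pool.pop()
                if (ev.key(),) not in used:
                    return (ev,)
        return None

    def take_insertion() -> tuple[SecondaryEvent, ...] | None:
        need = (-pathogenic.net_len) % 3  # net +k with (path + k) % 3 == 0
        ins_len = need if need else 3
        for _ in range(200):
            pos = int(
                rng.integers(
                    max(ref_seq.offset, pathogenic.pos - 50),
                    min(ref_seq.offset + len(ref_seq) - 2, pathogenic.pos + 50),
                )
            )
            anchor = ref_seq.base(pos)
            ins = "".join(rng.choice(list("ACGT"), size=ins_len))
            ev = left_align(SecondaryEvent(pos, anchor, anchor + ins), ref_seq)
            key = (ev.key(),)
            if key in used:
                continue
            if not _clear_of_pathogenic(ev, pathogenic):
                continue
            if not _frame_ok(ref_seq, pathogenic, (ev,)):
                continue
            return (ev,)
        return None

    def take_complex() -> tuple[SecondaryEvent, ...] | None:
        # two nearby deletions whose combined net restores the frame
        need = pathogenic.net_len % 3
        for _ in range(400):
            d1 = int(rng.integers(1, 7))
            d2 = int(rng.integers(1, 7))
            if (d1 + d2) % 3 != need:
                continue
            p1 = int(rng.integers(
                max(ref_seq.offset + 1, pathogenic.pos - 55), pathogenic.pos - 5
            ))
            p2 = int(rng.integers(pathogenic.pos + 5, pathogenic.pos + 55))
            try:
                e1 = left_align(
                    SecondaryEvent(p1 - 1, ref_seq.slice(p1 - 1, p1 - 1 + d1),
                                   ref_seq.base(p1 - 1)), ref_seq)
                e2 = left_align(
                    SecondaryEvent(p2 - 1, ref_seq.slice(p2 - 1, p2 - 1 + d2),
                                   ref_seq.base(p2 - 1)), ref_seq)
            except (ValueError, IndexError):
                continue
            pair = tuple(sorted((e1, e2), key=lambda e: e.pos))
            key = tuple(e.key() for e in pair)
            if key in used or key[0] == key[1]:
                continue
            if not all(_clear_of_pathogenic(e, pathogenic) for e in pair):
                continue
            if not _frame_ok(ref_seq, pathogenic, pair):
                continue
            return pair
        return None

    takers = (take_deletion, take_insertion, take_complex)
    probs = np.asarray(class_mix, dtype=float)
    probs = probs / probs.sum()
    attempts = 0
    while len(out) < n_events and attempts < 50 * n_events:
        attempts += 1
        choice = int(rng.choice(3, p=probs))
        ev = takers[choice]()
        if ev is None:
            ev = take_deletion() or take_insertion()
        if ev is None:
            continue
        key = tuple(e.key() for e in ev)
        if key in used:
            continue
        used.add(key)
        out.append(ev)
    if len(out) < n_events:
        raise RuntimeError("could not generate the requested number of reversions")
    return out


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def sim_reads(
    haplotypes: list[tuple[str, float]],
    depth: int,
    read_len: int = 150,
    err: float = 0.0,
    seed: int = 0,
    labels: list[str] | None = None,
    anchor: int | None = None,
    coord_offset: int = 1,
) -> list[Read]:
    """Amplicon-style single-end reads from a weighted haplotype mixture.

    Each read originates from haplotype h with probability weight(h) and covers
    the ``anchor`` position (default: haplotype midpoint), emulating a
    multiplex-PCR amplicon tiling the variant site at the full raw depth.
    Sequencing errors are uniform substitutions at rate ``err``; truth labels
    record the haplotype of origin. Byte-identical output for a fixed seed.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    weights = np.array([w for _, w in haplotypes], dtype=float)
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError("weights must sum to 1")
    for seq, _ in haplotypes:
        if read_len > len(seq):
            raise ValueError("read_len exceeds haplotype length")
    rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"hap{i}" for i in range(len(haplotypes))]
    origins = rng.choice(len(haplotypes), size=depth, p=weights)
    reads: list[Read] = []
    base_arr = np.array(list("ACGT"))
    for i, h in enumerate(origins):
        seq, _ = haplotypes[h]
        anc = (len(seq) // 2) if anchor is None else (anchor - coord_offset)
        lo = max(0, anc - read_len + 1)
        hi = min(len(seq) - read_len, anc)
        start0 = int(rng.integers(lo, hi + 1)) if hi >= lo else max(0, min(anc, len(seq) - read_len))
        frag = seq[start0 : start0 + read_len]
        if err > 0:
            frag_arr = np.array(list(frag))
            mask = rng.random(read_len) < err
            if mask.any():
                subs = rng.choice(base_arr, size=int(mask.sum()))
                # force a real change
                same = subs == frag_arr[mask]
                while same.any():
                    subs[same] = rng.choice(base_arr, size=int(same.sum()))
                    same = subs == frag_arr[mask]
                frag_arr[mask] = subs
                frag = "".join(frag_arr)
        quals = "".join(chr(33 + q) for q in rng.integers(28, 41, size=read_len))
        reads.append(
            Read(
                name=f"r{i:06d}",
                start=start0 + coord_offset,
                sequence=frag,
                qualities=quals,
                truth=labels[h],
            )
        )
    return reads


# ---------------------------------------------------------------------------
# Longitudinal trajectories
# ---------------------------------------------------------------------------

def _logistic(t: float, t0: float, af0: float, rate: float, cap: float) -> float:
    if t < t0:
        return 0.0
    return cap / (1.0 + (cap / af0 - 1.0) * math.exp(-rate * (t - t0)))


def truth_trajectory(params: TrajectoryParams, day: float) -> tuple[float, list[float]]:
    """Deterministic (pathogenic-clone AF, per-reversion AFs) at ``day``."""
    af0 = params.pathogenic_af0
    nadir_af = max(af0 * params.nadir_fraction, 1e-6)
    t_n = params.response_nadir_day
    if af0 <= 0:
        paf = 0.0
    elif day <= t_n or t_n <= 0:
        k = math.log(af0 / nadir_af) / t_n if t_n > 0 else 0.0
        paf = af0 * math.exp(-k * day)
    else:
        paf = _logistic(day, t_n, nadir_af, params.regrowth_rate, params.pathogenic_af_cap)
    rafs = [
        _logistic(day, b, 1e-3, r, params.reversion_af_cap)
        for b, r in zip(params.reversion_birth_times, params.reversion_growth_rates)
    ]
    total = paf + sum(rafs)
    if total > 0.95:  # keep a reference fraction
        scale = 0.95 / total
        paf *= scale
        rafs = [a * scale for a in rafs]
    return paf, rafs


def sim_longitudinal(
    scenario: LocusScenario,
    params: TrajectoryParams,
    timepoints: list[float],
    seed: int,
    read_len: int = 150,
    err: float = 0.0,
) -> tuple[dict[float, list[Read]], pd.DataFrame]:
    """Per-timepoint read sets plus the truth allele-frequency table.

    Haplotype weights at each day follow the deterministic clone trajectory;
    the observed AFs in the returned reads are then binomial draws at
    ``detection_depth`` around the truth by construction. Reversion clones
    retain the pathogenic lesion (secondary events arise on the mutant
    haplotype) except when the event itself removes the pathogenic site.
    """
    if not timepoints:
        raise ValueError("empty timepoints")
    if sorted(timepoints) != list(timepoints):
        raise ValueError("timepoints must be sorted ascending")
    locus = scenario.locus
    pathogenic = scenario.pathogenic
    hap_seqs = [locus.sequence, apply_events(locus, [pathogenic.as_event()])]
    hap_labels = ["ref", "pathogenic"]
    for i, events in enumerate(scenario.reversions):
        if any(spans_pathogenic(e, pathogenic) for e in events):
            applied = list(events)
        else:
            applied = sorted((*events, pathogenic.as_event()), key=lambda e: e.pos)
        hap_seqs.append(apply_events(locus, applied))
        hap_labels.append(f"rev{i}")

    n_rev = len(scenario.reversions)
    if len(params.reversion_birth_times) != n_rev:
        raise ValueError("params must carry one birth time per reversion event")

    rng = np.random.default_rng(seed)
    read_sets: dict[float, list[Read]] = {}
    rows = []
    for day in timepoints:
        paf, rafs = truth_trajectory(params, day)
        w = np.array([1.0 - paf - sum(rafs), paf, *rafs])
        w = np.clip(w, 0.0, None)
        w = w / w.sum()
        reads = sim_reads(
            [(s, wi) for s, wi in zip(hap_seqs, w)],
            depth=params.detection_depth,
            read_len=read_len,
            err=err,
            seed=int(rng.integers(2**31 - 1)),
            labels=hap_labels,
            anchor=pathogenic.pos,
            coord_offset=locus.offset,
        )
        read_sets[day] = reads
        rows.append(
            {"day": day, "clone": "pathogenic", "true_af": paf,
             "observed_af": sum(r.truth == "pathogenic" for r in reads) / len(reads)}
        )
        for i, raf in enumerate(rafs):
            rows.append(
                {"day": day, "clone": f"rev{i}", "true_af": raf,
                 "observed_af": sum(r.truth == f"rev{i}" for r in reads) / len(reads)}
            )
    return read_sets, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Survival simulation
# ---------------------------------------------------------------------------

def sim_survival(
    reversion_trajectories: list[list[tuple[float, int]]],
    params: SurvivalSimParams,
    horizon_months: float = 120.0,
) -> pd.DataFrame:
    """Survival table from a piecewise-constant-hazard model.

    Each patient's covariate is a right-continuous step function of time in
    months, given as (time, count) breakpoints starting at time 0. Event times
    are drawn from hazard lambda(t) = h0 * exp(beta * count(t)) by
    piecewise-exponential inversion; censoring is exponential at
    ``censor_rate`` (0 = no censoring) truncated at ``horizon_months``.
    """
    rng = np.random.default_rng(params.seed)
    h0 = params.baseline_hazard
    beta = params.log_hr_per_reversion
    rows = []
    for pid, steps in enumerate(reversion_trajectories):
        if not steps or steps[0][0] != 0:
            raise ValueError("each trajectory must start with a (0, count) step")
        times = [t for t, _ in steps] + [math.inf]
        counts = [c for _, c in steps]
        target = rng.exponential(1.0)  # unit-exponential cumulative hazard
        cum = 0.0
        t_event = math.inf
        for k in range(len(counts)):
            rate = h0 * math.exp(beta * counts[k])
            width = times[k + 1] - times[k]
            seg = rate * width
            if cum + seg >= target:
                t_event = times[k] + (target - cum) / rate if rate > 0 else math.inf
                break
            cum += seg
        t_cens = (
            rng.exponential(1.0 / params.censor_rate)
            if params.censor_rate > 0
            else math.inf
        )
        t_cens = min(t_cens, horizon_months)
        time = min(t_event, t_cens)
        event = int(t_event <= t_cens)
        rows.append({"patient": f"p{pid:03d}", "time_months": time, "event": event})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# BAF / logR track simulation
# ---------------------------------------------------------------------------

def sim_baf_logr(
    params: CNSimParams,
) -> tuple["cnclone.SegmentTrack", "cnclone.SegmentTrack", dict]:
    """Baseline and end-of-treatment BAF/logR tracks for the target locus.

    The baseline track carries a clonal homozygous deletion (state (0,0) in
    every tumor cell); the end-of-treatment track mixes the homozygously
    deleted state at fraction ``homdel_fraction`` with ``background_state`` in
    the remaining tumor cells. Per-bin means equal the closed-form expected
    signal of the mixture; Gaussian noise is added and BAF clipped to [0,1].
    Returns (baseline, eot, truth).
    """
    rng = np.random.default_rng(params.seed)
    mixes = {
        "baseline": cnclone.StateMixture(
            state1=(0, 0), state2=params.background_state, f=1.0,
            purity=params.purity, ploidy=params.ploidy,
        ),
        "eot": cnclone.StateMixture(
            state1=(0, 0), state2=params.background_state, f=params.homdel_fraction,
            purity=params.purity, ploidy=params.ploidy,
        ),
    }
    tracks = {}
    for name, mix in mixes.items():
        sig = cnclone.expected_signal(mix)
        baf = np.clip(
            sig.baf + rng.normal(0.0, params.baf_noise_sd, params.n_bins), 0.0, 1.0
        )
        # phased germline BAF: flip each bin's labelled allele at random
        flip = rng.random(params.n_bins) < 0.5
        baf = np.where(flip, 1.0 - baf, baf)
        logr = sig.logr + rng.normal(0.0, params.logr_noise_sd, params.n_bins)
        starts = params.bin_start + params.bin_size * np.arange(params.n_bins)
        bins = pd.DataFrame(
            {
                "contig": params.contig,
                "start": starts,
                "end": starts + params.bin_size - 1,
                "baf": baf,
                "logr": logr,
            }
        )
        tracks[name] = cnclone.SegmentTrack(
            sample=name, bins=bins, purity=params.purity, ploidy=params.ploidy
        )
    truth = {
        "baseline_f": 1.0,
        "eot_f": params.homdel_fraction,
        "background_state": params.background_state,
        "expected_baseline": cnclone.expected_signal(mixes["baseline"]),
        "expected_eot": cnclone.expected_signal(mixes["eot"]),
    }
    return tracks["baseline"], tracks["eot"], truth
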