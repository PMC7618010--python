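"""Reversion-mutation detection around a known pathogenic variant.

A tumor inactivated by a pathogenic frameshift or stop-gain lesion can regain
protein function through a *reversion*: a secondary event that restores the
native reading frame (for frameshifts: indels whose net length, combined with
the pathogenic lesion, is 0 mod 3; for stop-gains: substitutions replacing the
premature stop with a non-stop, non-reference codon). This module detects such
events from targeted-panel reads by candidate discovery (read-vs-reference
alignment), haplotype enumeration, quality-masked read realignment against each
candidate haplotype, and support-filtered calling. Deletion junctions are
annotated for flanking microhomology, the scar of polymerase-theta-mediated
end joining (MMEJ).

Coordinates are 1-based inclusive throughout; indels use the VCF anchored
representation and are left-aligned before comparison or microhomology calling.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import edlib
import numpy as np

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_DNA = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusReference:
    """A reference locus sequence with its genomic start coordinate.

    The sequence is assumed to begin on a codon boundary (frame 0 at the
    first base), as for a CDS-centred extraction window.
    """

    name: str
    sequence: str
    offset: int = 1  # 1-based genomic coordinate of sequence[0]

    def __post_init__(self) -> None:
        if not set(self.sequence) <= _DNA:
            bad = sorted(set(self.sequence) - _DNA)
            raise ValueError(f"non-ACGT characters in reference: {bad}")

    def __len__(self) -> int:
        return len(self.sequence)

    def base(self, pos: int) -> str:
        """Base at 1-based genomic position ``pos``."""
        return self.sequence[pos - self.offset]

    def slice(self, start: int, end: int) -> str:
        """Sequence for the 1-based inclusive interval [start, end]."""
        return self.sequence[start - self.offset : end - self.offset + 1]


@dataclass(frozen=True)
class SecondaryEvent:
    """A candidate secondary lesion in VCF anchored representation."""

    pos: int          # 1-based position of the anchor (first ref base)
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref and not self.alt:
            raise ValueError("event with empty ref and alt")

    @property
    def net_len(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return self.net_len < 0 and self.alt == self.ref[: len(self.alt)]

    @property
    def is_insertion(self) -> bool:
        return self.net_len > 0 and self.ref == self.alt[: len(self.ref)]

    @property
    def is_substitution(self) -> bool:
        return self.net_len == 0 and self.ref != self.alt

    @property
    def ref_span(self) -> tuple[int, int]:
        """1-based inclusive interval of reference bases the event replaces."""
        return self.pos, self.pos + len(self.ref) - 1

    @property
    def deleted_span(self) -> tuple[int, int] | None:
        """Interval of deleted bases (excluding the anchor), or None."""
        if not self.is_deletion:
            return None
        return self.pos + len(self.alt), self.pos + len(self.ref) - 1

    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class PathogenicVariant:
    """The enrolling pathogenic lesion that anchors reversion calling.

    Frameshift lesions are anchored indels (net length not 0 mod 3).
    Stop-gain lesions are represented codon-wise: ``pos`` is the first base of
    the affected codon, ``ref`` the reference codon and ``alt`` the premature
    stop codon.
    """

    gene: str
    contig: str
    pos: int
    ref: str
    alt: str
    klass: str  # "frameshift" | "stop_gain"
    origin: str = "somatic"  # "germline" | "somatic"

    def __post_init__(self) -> None:
        if self.klass not in ("frameshift", "stop_gain"):
            raise ValueError(f"unknown pathogenic class {self.klass!r}")
        if self.klass == "frameshift":
            if self.net_len % 3 == 0:
                raise ValueError("frameshift lesion must change length by != 0 mod 3")
        else:
            if self.net_len != 0 or self.alt not in STOP_CODONS:
                raise ValueError("stop-gain lesion must be a codon substitution to a stop codon")

    @property
    def net_len(self) -> int:
        return len(self.alt) - len(self.ref)

    @property
    def cds_frame(self) -> int:
        """Offset of pos within its codon, assuming frame 0 at coordinate 1."""
        return (self.pos - 1) % 3

    def as_event(self) -> SecondaryEvent:
        return SecondaryEvent(self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class RealignConfig:
    """Parameters of the realignment-based reversion caller."""

    window: int = 4000            # nt each side of the pathogenic variant
    min_qual: int = 20            # phred cutoff; lower-quality bases are masked
    min_percent_realigned: float = 0.9   # percent of reads, sample-level QC
    min_nt_distant: int = 15      # min aligned nt for distant-event support
    allow_insertions: bool = True
    max_combo: int = 2            # max secondary events per haplotype
    min_support: int = 3          # read-support floor for any reported call

    def __post_init__(self) -> None:
        if self.window <= 0:
            raise ValueError("window must be positive")
        if self.min_qual < 0:
            raise ValueError("min_qual must be >= 0")


@dataclass
class Read:
    """A single-end panel read with per-base qualities and optional truth label."""

    name: str
    start: int                    # 1-based leftmost reference coordinate (approximate)
    sequence: str
    qualities: str                # phred+33 string, same length as sequence
    truth: str | None = None      # haplotype-of-origin label, if simulated

    def qual_array(self) -> np.ndarray:
        return np.frombuffer(self.qualities.encode(), dtype=np.uint8).astype(int) - 33


@dataclass(frozen=True)
class Haplotype:
    """A candidate local haplotype: reference with a set of events applied."""

    name: str
    events: tuple[SecondaryEvent, ...]
    sequence: str
    frame_restored: bool
    includes_pathogenic: bool


@dataclass
class ReversionCall:
    """A reported reversion with classification, support and MH annotation."""

    events: tuple[SecondaryEvent, ...]
    klass: str                     # deletion | insertion | complex | stopgain_substitution
    support_reads: int
    total_reads: int
    mh_len: int | None = None
    mmej_consistent: bool = False
    first_seen: str | None = None
    baseline_detected: bool = False
    qc_flags: tuple[str, ...] = ()

    @property
    def af(self) -> float:
        return self.support_reads / self.total_reads if self.total_reads else 0.0

    def event_key(self) -> tuple:
        return tuple(e.key() for e in self.events)


@dataclass
class AssignmentTable:
    """Per-haplotype read counts from quality-masked realignment."""

    haplotypes: list[Haplotype]
    counts: dict[str, int]
    n_assigned: int
    n_unassigned: int
    percent_realigned: float      # percent of reads best-explained by a reversion haplotype


# ---------------------------------------------------------------------------
# Event normalisation and frame arithmetic
# ---------------------------------------------------------------------------

def left_align(event: SecondaryEvent, ref_seq: LocusReference) -> SecondaryEvent:
    """Return the leftmost anchored representation of ``event``.

    Uses the standard variant-normalisation loop: trim shared trailing bases
    (extending left with the previous reference base when one allele empties),
    then trim shared leading bases. Substitutions are returned unchanged.
    Idempotent, and the haplotype produced by the event is preserved.
    """
    lo, hi = event.ref_span
    if event.ref and ref_seq.slice(lo, hi) != event.ref:
        raise ValueError(
            f"event ref {event.ref!r} at {event.pos} disagrees with reference "
            f"{ref_seq.slice(lo, hi)!r}"
        )
    if event.is_substitution:
        return event
    pos, ref, alt = event.pos, event.ref, event.alt
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos <= ref_seq.offset:
                    break  # cannot extend further left
                pos -= 1
                prev = ref_seq.base(pos)
                ref, alt = prev + ref, prev + alt
        elif len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        else:
            break
    return SecondaryEvent(pos, ref, alt)


def events_overlap(a: SecondaryEvent, b: SecondaryEvent) -> bool:
    a_lo, a_hi = a.ref_span
    b_lo, b_hi = b.ref_span
    return a_lo <= b_hi and b_lo <= a_hi


def spans_pathogenic(event: SecondaryEvent, pathogenic: PathogenicVariant) -> bool:
    """True when the event's deleted bases remove the pathogenic site."""
    span = event.deleted_span
    if span is None:
        return False
    return span[0] <= pathogenic.pos <= span[1]


def net_frame_change(
    pathogenic: PathogenicVariant, events: Sequence[SecondaryEvent]
) -> int:
    """Reading-frame shift (mod 3) of the haplotype carrying pathogenic + events.

    When an event deletes the pathogenic site, the pathogenic lesion no longer
    contributes and the shift is the summed net length of the events alone.
    """
    for a, b in itertools.combinations(events, 2):
        if events_overlap(a, b):
            raise ValueError(f"overlapping events {a} and {b}")
    if any(spans_pathogenic(e, pathogenic) for e in events):
        return sum(e.net_len for e in events) % 3
    return (pathogenic.net_len + sum(e.net_len for e in events)) % 3


def apply_events(ref_seq: LocusReference, events: Sequence[SecondaryEvent]) -> str:
    """Reference sequence with non-overlapping events applied."""
    ordered = sorted(events, key=lambda e: e.pos)
    for a, b in zip(ordered, ordered[1:]):
        if events_overlap(a, b):
            raise ValueError(f"overlapping events {a} and {b}")
    out: list[str] = []
    cursor = ref_seq.offset
    for ev in ordered:
        lo, hi = ev.ref_span
        if ev.ref and ref_seq.slice(lo, hi) != ev.ref:
            raise ValueError(f"event ref mismatch at {ev.pos}")
        out.append(ref_seq.slice(cursor, lo - 1))
        out.append(ev.alt)
        cursor = hi + 1
    out.append(ref_seq.slice(cursor, ref_seq.offset + len(ref_seq) - 1))
    return "".join(out)


def has_premature_stop(haplotype: str, from_index: int) -> bool:
    """Any stop codon in frame 0 from the codon containing ``from_index`` on.

    ``from_index`` is a 0-based index into ``haplotype``; trailing partial
    codons are ignored.
    """
    start = (from_index // 3) * 3
    for i in range(start, len(haplotype) - 2, 3):
        if haplotype[i : i + 3] in STOP_CODONS:
            return True
    return False


# ---------------------------------------------------------------------------
# Haplotype enumeration
# ---------------------------------------------------------------------------

def _hap_index(events: Sequence[SecondaryEvent], ref_pos: int, offset: int) -> int:
    """0-based haplotype index corresponding to reference position ``ref_pos``."""
    shift = 0
    for ev in events:
        if ev.ref_span[1] < ref_pos:
            shift += ev.net_len
    return ref_pos - offset + shift


def enumerate_candidate_haplotypes(
    pathogenic: PathogenicVariant,
    candidates: Sequence[SecondaryEvent],
    cfg: RealignConfig,
    ref_seq: LocusReference,
) -> list[Haplotype]:
    """All local haplotypes worth scoring reads against.

    Always includes the reference and pathogenic haplotypes. For frameshift
    lesions it adds every pathogenic + event-combination haplotype (up to
    ``max_combo`` events) whose combined frame change is 0 mod 3, plus
    pathogenic-spanning deletions with net change 0 mod 3 applied alone; each
    restored haplotype must show no premature stop codon between the pathogenic
    site and the window end. For stop-gain lesions it adds one haplotype per
    candidate non-stop, non-reference codon substitution at the pathogenic codon.
    """
    lo = ref_seq.offset
    hi = ref_seq.offset + len(ref_seq) - 1
    if not (lo <= pathogenic.pos <= hi):
        raise ValueError("window does not contain the pathogenic site")

    path_event = pathogenic.as_event()
    haps: list[Haplotype] = [
        Haplotype("ref", (), ref_seq.sequence, False, False),
        Haplotype("pathogenic", (path_event,), apply_events(ref_seq, [path_event]), False, True),
    ]
    seen: set[tuple] = set()
    # distinct event combinations can yield an identical haplotype sequence
    # (e.g. alternative decompositions in repeats); keep the first, so reads
    # are not split across indistinguishable targets
    seen_seqs: set[str] = {h.sequence for h in haps}

    if pathogenic.klass == "stop_gain":
        for ev in candidates:
            if not (ev.is_substitution and len(ev.ref) == 3 and ev.pos == pathogenic.pos):
                continue
            if ev.alt in STOP_CODONS or ev.alt == pathogenic.ref:
                continue
            key = (ev.key(),)
            if key in seen:
                continue
            seen.add(key)
            seq = apply_events(ref_seq, [ev])
            haps.append(Haplotype(f"rev_{ev.pos}_{ev.ref}>{ev.alt}", (ev,), seq, True, False))
        return haps

    usable = [
        ev for ev in candidates
        if cfg.allow_insertions or not ev.is_insertion
    ]
    path_site = pathogenic.pos

    # pathogenic-retaining combinations
    for k in range(1, cfg.max_combo + 1):
        for combo in itertools.combinations(usable, k):
            if any(spans_pathogenic(ev, pathogenic) for ev in combo):
                continue
            if any(events_overlap(ev, path_event) for ev in combo):
                continue
            if any(events_overlap(a, b) for a, b in itertools.combinations(combo, 2)):
                continue
            if (pathogenic.net_len + sum(ev.net_len for ev in combo)) % 3 != 0:
                continue
            key = tuple(sorted(ev.key() for ev in combo))
            if key in seen:
                continue
            seen.add(key)
            all_events = sorted(combo + (path_event,), key=lambda e: e.pos)
            seq = apply_events(ref_seq, all_events)
            if seq in seen_seqs:
                continue
            first = min(path_site, min(ev.pos for ev in combo))
            if has_premature_stop(seq, _hap_index(all_events, first, ref_seq.offset)):
                continue
            seen_seqs.add(seq)
            name = "rev_" + "+".join(f"{e.pos}_{e.ref}>{e.alt}" for e in combo)
            haps.append(Haplotype(name, tuple(combo), seq, True, True))

    # pathogenic-spanning deletions, applied alone
    for ev in usable:
        if not spans_pathogenic(ev, pathogenic):
            continue
        if ev.net_len % 3 != 0:
            continue
        key = (("span",) + ev.key(),)
        if key in seen:
            continue
        seen.add(key)
        seq = apply_events(ref_seq, [ev])
        if seq in seen_seqs:
            continue
        if has_premature_stop(seq, _hap_index([ev], ev.pos, ref_seq.offset)):
            continue
        seen_seqs.add(seq)
        name = f"rev_span_{ev.pos}_{ev.ref}>{ev.alt}"
        haps.append(Haplotype(name, (ev,), seq, True, False))

    return haps


# ---------------------------------------------------------------------------
# Candidate discovery from reads
# ---------------------------------------------------------------------------

def _cigar_walk(cigar: str):
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
        else:
            yield int(num), ch
            num = ""


def _affine_aligner():
    """Infix aligner with affine gaps, so long deletions stay contiguous."""
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -2.0
    aligner.open_gap_score = -6.0
    aligner.extend_gap_score = -0.2
    # free end gaps on the target window only: the read aligns as an infix of
    # the reference ("deletions" at the window flanks cost nothing, read ends
    # may not be clipped for free)
    for attr, legacy in (
        ("open_left_deletion_score", "query_left_open_gap_score"),
        ("extend_left_deletion_score", "query_left_extend_gap_score"),
        ("open_right_deletion_score", "query_right_open_gap_score"),
        ("extend_right_deletion_score", "query_right_extend_gap_score"),
    ):
        try:
            setattr(aligner, attr, 0.0)
        except AttributeError:
            setattr(aligner, legacy, 0.0)
    return aligner


def discover_candidate_events(
    reads: Iterable[Read],
    ref_seq: LocusReference,
    cfg: RealignConfig,
    min_occurrences: int = 3,
    pathogenic: PathogenicVariant | None = None,
    pad: int = 80,
) -> list[SecondaryEvent]:
    """Indel candidates from read-vs-reference alignments within the window.

    Reads that are exact substrings of the reference (or of the pathogenic
    haplotype, when given) carry no novel events and are skipped. The rest are
    infix-aligned against a local reference window with affine gap penalties —
    unit-cost edit distance would shatter long deletions into spurious
    fragments — and indels in the alignment are collected as anchored,
    left-aligned events. Events seen in at least ``min_occurrences`` reads are
    returned (the 3-read call floor is applied later, on realignment support).
    """
    tally: dict[tuple[int, str, str], int] = {}
    target = ref_seq.sequence
    path_seq = (
        apply_events(ref_seq, [pathogenic.as_event()]) if pathogenic is not None else None
    )
    aligner = _affine_aligner()
    for read in reads:
        if read.sequence in target:
            continue
        if path_seq is not None and read.sequence in path_seq:
            continue
        lo = max(0, read.start - ref_seq.offset - pad)
        hi = min(len(target), read.start - ref_seq.offset + len(read.sequence) + pad)
        window = target[lo:hi]
        try:
            aln = aligner.align(window, read.sequence)[0]
        except (IndexError, ValueError):
            continue
        t_blocks, q_blocks = aln.aligned
        for k in range(1, len(t_blocks)):
            t_gap = t_blocks[k][0] - t_blocks[k - 1][1]
            q_gap = q_blocks[k][0] - q_blocks[k - 1][1]
            tpos = int(t_blocks[k - 1][1])  # 0-based window coord after previous block
            if lo + tpos == 0:
                continue
            anchor = target[lo + tpos - 1]
            if t_gap > 0 and q_gap == 0:  # deletion from the reference
                ev = SecondaryEvent(
                    ref_seq.offset + lo + tpos - 1,
                    anchor + window[tpos : tpos + t_gap],
                    anchor,
                )
            elif q_gap > 0 and t_gap == 0:  # insertion in the read
                qpos = int(q_blocks[k - 1][1])
                ev = SecondaryEvent(
                    ref_seq.offset + lo + tpos - 1,
                    anchor,
                    anchor + read.sequence[qpos : qpos + q_gap],
                )
            else:
                continue
            ev = left_align(ev, ref_seq)
            tally[ev.key()] = tally.get(ev.key(), 0) + 1
    return [
        SecondaryEvent(*key)
        for key, n in sorted(tally.items())
        if n >= min_occurrences
    ]


# ---------------------------------------------------------------------------
# Read assignment (quality-masked realignment)
# ---------------------------------------------------------------------------

def _score_read_against(
    read_seq: str, quals: np.ndarray, hap_window: str, min_qual: int
) -> tuple[int, int]:
    """(quality-masked mismatch+gap count, aligned read bases) for best infix fit."""
    res = edlib.align(read_seq, hap_window, mode="HW", task="path")
    if res["editDistance"] < 0:
        return len(read_seq), 0
    qpos = 0
    penalty = 0
    aligned = 0
    for n, op in _cigar_walk(res["cigar"]):
        if op == "=":
            aligned += n
            qpos += n
        elif op == "X":
            penalty += int(np.count_nonzero(quals[qpos : qpos + n] >= min_qual))
            aligned += n
            qpos += n
        elif op == "I":
            penalty += n
            qpos += n
        elif op == "D":
            penalty += n
    return penalty, aligned


def assign_reads(
    reads: Sequence[Read],
    haplotypes: Sequence[Haplotype],
    cfg: RealignConfig,
    ref_offset: int = 1,
) -> AssignmentTable:
    """Assign each read to its best haplotype under a quality-masked score.

    Bases below ``min_qual`` are ignored when counting mismatches; alignment
    gaps always count. A read is assigned to the unique minimum-penalty
    haplotype. When several haplotypes tie, the tie is resolved by parsimony:
    if one tied haplotype's event set is a subset of every other tied
    haplotype's (e.g. a read consistent with both the pathogenic haplotype and
    a reversion haplotype whose extra event it does not cover), the read goes
    to that least-specific haplotype; otherwise it is left unassigned, so
    ambiguous evidence never supports a call. Support for a reversion
    haplotype additionally requires the read to overlap one of its
    non-pathogenic events and to align at least ``min_nt_distant`` bases.
    """
    if not haplotypes:
        raise ValueError("empty haplotype list")
    counts: dict[str, int] = {h.name: 0 for h in haplotypes}
    pad = 60
    n_unassigned = 0

    # precompute per-haplotype coordinate shift breakpoints for local slicing
    hap_events = [sorted(h.events, key=lambda e: e.pos) for h in haplotypes]
    eff_events = [
        {e.key() for e in h.events} | ({("pathogenic",)} if h.includes_pathogenic else set())
        for h in haplotypes
    ]

    def resolve_tie(tied: list[int]) -> int | None:
        minimal = [
            i for i in tied
            if all(eff_events[i] <= eff_events[j] for j in tied)
        ]
        return minimal[0] if len(minimal) == 1 else None

    for read in reads:
        quals = read.qual_array()
        rlen = len(read.sequence)
        tied: list[int] = []
        best_penalty: int | None = None
        best_aligned = rlen

        # fast path: with no maskable bases, penalty 0 means exact substring
        if int(quals.min(initial=99)) >= cfg.min_qual:
            tied = [ih for ih, hap in enumerate(haplotypes) if read.sequence in hap.sequence]
            if tied:
                best_penalty = 0
        if best_penalty is None:
            tied = []
            aligned_by_hap = {}
            for ih, hap in enumerate(haplotypes):
                # local window on the haplotype around the read's expected position
                shift = sum(
                    ev.net_len for ev in hap_events[ih] if ev.ref_span[1] < read.start
                )
                h0 = read.start - ref_offset + shift
                lo = max(0, h0 - pad)
                hi = min(len(hap.sequence), h0 + rlen + pad)
                penalty, aligned = _score_read_against(
                    read.sequence, quals, hap.sequence[lo:hi], cfg.min_qual
                )
                aligned_by_hap[ih] = aligned
                if best_penalty is None or penalty < best_penalty:
                    best_penalty = penalty
                    tied = [ih]
                elif penalty == best_penalty:
                    tied.append(ih)
            best_aligned = aligned_by_hap[tied[0]] if tied else 0
        winner = tied[0] if len(tied) == 1 else resolve_tie(tied)
        if winner is None:
            n_unassigned += 1
            continue
        hap = haplotypes[winner]
        if hap.frame_restored:
            rd_lo, rd_hi = read.start, read.start + rlen - 1
            overlaps = any(
                e.ref_span[0] - 1 <= rd_hi and rd_lo <= e.ref_span[1] + 1
                for e in hap.events
            )
            if not overlaps or best_aligned < cfg.min_nt_distant:
                n_unassigned += 1
                continue
        counts[hap.name] += 1

    n_assigned = sum(counts.values())
    n_rev = sum(
        counts[h.name] for h in haplotypes if h.frame_restored
    )
    pct = 100.0 * n_rev / n_assigned if n_assigned else 0.0
    return AssignmentTable(
        haplotypes=list(haplotypes),
        counts=counts,
        n_assigned=n_assigned,
        n_unassigned=n_unassigned,
        percent_realigned=pct,
    )


# ---------------------------------------------------------------------------
# Calling
# ---------------------------------------------------------------------------

def _classify_events(events: tuple[SecondaryEvent, ...]) -> str:
    if len(events) == 1 and events[0].is_substitution and len(events[0].ref) == 3:
        return "stopgain_substitution"
    if len(events) >= 2:
        return "complex"
    ev = events[0]
    if ev.is_deletion:
        return "deletion"
    if ev.is_insertion:
        return "insertion"
    return "complex"


def call_reversions(
    assignment: AssignmentTable,
    cfg: RealignConfig,
    ref_seq: LocusReference | None = None,
) -> list[ReversionCall]:
    """One call per frame-restored haplotype passing the 3-read support floor.

    Allele frequency is computed over all assigned reads at the locus. Calls in
    a sample whose overall realigned-read percentage falls below
    ``min_percent_realigned`` (in percent of reads) carry a QC flag rather than
    being dropped. Single-deletion calls of 2+ nt are annotated for junction
    microhomology when the reference is supplied.
    """
    total = assignment.n_assigned
    flags: tuple[str, ...] = ()
    if assignment.percent_realigned < cfg.min_percent_realigned:
        flags = ("low_realignment_fraction",)
    calls: list[ReversionCall] = []
    for hap in assignment.haplotypes:
        if not hap.frame_restored:
            continue
        support = assignment.counts[hap.name]
        if support < cfg.min_support:
            continue
        call = ReversionCall(
            events=hap.events,
            klass=_classify_events(hap.events),
            support_reads=support,
            total_reads=total,
            qc_flags=flags,
        )
        if (
            ref_seq is not None
            and call.klass == "deletion"
            and hap.events[0].net_len <= -2
        ):
            call.mh_len, call.mmej_consistent = microhomology(hap.events[0], ref_seq)
        calls.append(call)
    calls.sort(key=lambda c: (-c.support_reads, c.event_key()))
    return calls


def classify_stopgain(
    pileup: dict[str, int],
    ref_codon: str,
    pathogenic_codon: str,
    min_support: int = 3,
    total_reads: int | None = None,
) -> list[ReversionCall]:
    """Reversion calls from a codon-level pileup at a stop-gain site.

    A codon qualifies when it is (a) not a stop codon, (b) not the reference
    codon, (c) not the pathogenic codon, and is seen in at least
    ``min_support`` reads covering all three codon positions.
    """
    if pathogenic_codon not in STOP_CODONS:
        raise ValueError(f"{pathogenic_codon!r} is not a stop codon")
    total = total_reads if total_reads is not None else sum(pileup.values())
    calls = []
    for codon, n in sorted(pileup.items()):
        if codon in STOP_CODONS or codon in (ref_codon, pathogenic_codon):
            continue
        if n < min_support:
            continue
        ev = SecondaryEvent(pos=0, ref=ref_codon, alt=codon)
        calls.append(
            ReversionCall(
                events=(ev,),
                klass="stopgain_substitution",
                support_reads=n,
                total_reads=total,
            )
        )
    calls.sort(key=lambda c: -c.support_reads)
    return calls


def codon_pileup(
    reads: Iterable[Read], ref_seq: LocusReference, codon_pos: int
) -> dict[str, int]:
    """Tally of codons observed at ``codon_pos`` (1-based first base).

    Only reads covering all three codon positions contribute. Exact reference
    substrings are placed by direct lookup; the rest are infix-aligned with
    affine gap penalties, which keeps substitutions as substitutions (unit-cost
    edit distance can represent a double substitution as an indel pair,
    shifting the codon mapping).
    """
    tally: dict[str, int] = {}
    target = ref_seq.sequence
    want = [codon_pos - ref_seq.offset + k for k in range(3)]
    aligner = _affine_aligner()
    pad = 80
    for read in reads:
        mapping: dict[int, int] = {}
        idx = target.find(read.sequence)
        if idx >= 0:
            for q in range(len(read.sequence)):
                mapping[idx + q] = q
        else:
            lo = max(0, read.start - ref_seq.offset - pad)
            hi = min(len(target), read.start - ref_seq.offset + len(read.sequence) + pad)
            try:
                aln = aligner.align(target[lo:hi], read.sequence)[0]
            except (IndexError, ValueError):
                continue
            t_blocks, q_blocks = aln.aligned
            for (t0, t1), (q0, q1) in zip(t_blocks, q_blocks):
                for k in range(t1 - t0):
                    mapping[lo + t0 + k] = q0 + k
        if all(w in mapping for w in want):
            codon = "".join(read.sequence[mapping[w]] for w in want)
            tally[codon] = tally.get(codon, 0) + 1
    return tally


# ---------------------------------------------------------------------------
# Microhomology
# ---------------------------------------------------------------------------

def microhomology(
    deletion: SecondaryEvent, ref_seq: LocusReference, mmej_range: tuple[int, int] = (2, 6)
) -> tuple[int, bool]:
    """Junction microhomology length of a left-aligned multi-nt deletion.

    The MH length is the longer of two junction comparisons: the 5' end of the
    deleted sequence against the retained sequence immediately 3' of the
    deletion, and the 3' end of the deleted sequence against the retained
    sequence immediately 5'. Capped at the deletion length. Deletions with MH
    in ``mmej_range`` (2-6 nt by default) are flagged MMEJ-consistent.
    Single-nucleotide deletions are not evaluable.
    """
    if not deletion.is_deletion or deletion.net_len > -2:
        raise ValueError("microhomology requires a deletion of at least 2 nt")
    lo, hi = deletion.deleted_span
    deleted = ref_seq.slice(lo, hi)
    d = len(deleted)
    end = ref_seq.offset + len(ref_seq) - 1

    right_flank = ref_seq.slice(hi + 1, min(hi + d, end))
    mh5 = 0
    while mh5 < len(right_flank) and deleted[mh5] == right_flank[mh5]:
        mh5 += 1

    left_flank = ref_seq.slice(max(lo - d, ref_seq.offset), lo - 1)
    mh3 = 0
    while (
        mh3 < len(left_flank)
        and deleted[d - 1 - mh3] == left_flank[len(left_flank) - 1 - mh3]
    ):
        mh3 += 1

    mh = min(max(mh5, mh3), d)
    return mh, (mmej_range[0] <= mh <= mmej_range[1])


# ---------------------------------------------------------------------------
# High-level driver
# ---------------------------------------------------------------------------

def detect_reversions(
    reads: Sequence[Read],
    ref_seq: LocusReference,
    pathogenic: PathogenicVariant,
    cfg: RealignConfig | None = None,
) -> tuple[list[ReversionCall], AssignmentTable | None]:
    """End-to-end reversion detection for one sample.

    Frameshift lesions go through candidate discovery, haplotype enumeration
    and realignment; stop-gain lesions through codon-level pileup tallying.
    """
    cfg = cfg or RealignConfig()
    if pathogenic.klass == "stop_gain":
        pileup = codon_pileup(reads, ref_seq, pathogenic.pos)
        calls = classify_stopgain(
            pileup, pathogenic.ref, pathogenic.alt, min_support=cfg.min_support
        )
        for call in calls:
            ev = call.events[0]
            call.events = (SecondaryEvent(pathogenic.pos, ev.ref, ev.alt),)
        return calls, None
    candidates = discover_candidate_events(reads, ref_seq, cfg, pathogenic=pathogenic)
    haps = enumerate_candidate_haplotypes(pathogenic, candidates, cfg, ref_seq)
    table = assign_reads(reads, haps, cfg, ref_offset=ref_seq.offset)
    calls = call_reversions(table, cfg, ref_seq)
    return calls, table
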