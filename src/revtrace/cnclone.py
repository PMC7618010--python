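"""Homozygous-deletion subclone quantification from BAF/logR tracks.

A locus-level allele-specific copy-number model: a tumor of purity rho and
mean ploidy psi contains a fraction f of cells in allele-specific state
(n1A, n1B) — here fixed to the homozygous deletion (0,0) — and 1-f in a
background state (n2A, n2B). The expected per-bin signals are

    nbar = f*(n1A+n1B) + (1-f)*(n2A+n2B)
    logR = log2( (2*(1-rho) + rho*nbar) / (2*(1-rho) + rho*psi) )
    BAF  = ( (1-rho) + rho*(f*n1B + (1-f)*n2B) ) / ( 2*(1-rho) + rho*nbar )

A clonal homozygous deletion therefore shows BAF 0.5 (only germline alleles
remain) with a deeply negative logR; emergence of copy-retaining subclones
pulls logR up and disperses the phased BAF. The module jointly segments
multi-sample tracks by exact penalized least squares, fits the mixture
fraction per segment by grid search with bootstrap confidence intervals,
reconciles per-sample ploidy estimates, and intersects segments with gene
coordinates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SegmentTrack",
    "StateMixture",
    "GeneCall",
    "ExpectedSignal",
    "LocusMixtureFit",
    "PloidyFit",
    "expected_signal",
    "multisample_pcf",
    "fit_locus_mixture",
    "reconcile_ploidy",
    "genes_overlap",
]

CLONAL_MIN_F = 0.95
DEEP_DELETION_LOGR = -2.0  # segment log2 ratio below this flags a deep deletion


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SegmentTrack:
    """Binned BAF/logR values for one sample plus purity/ploidy estimates."""

    sample: str
    bins: pd.DataFrame  # columns: contig, start, end, baf, logr
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        required = {"contig", "start", "end", "baf", "logr"}
        if not required <= set(self.bins.columns):
            raise ValueError(f"bins must carry columns {sorted(required)}")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0,1]")
        starts = self.bins["start"].to_numpy()
        if np.any(np.diff(starts) <= 0):
            raise ValueError("bins must be sorted and non-overlapping")
        baf = self.bins["baf"].to_numpy()
        if np.any((baf < 0) | (baf > 1)):
            raise ValueError("BAF values must lie in [0,1]")


@dataclass(frozen=True)
class StateMixture:
    """Two-state allele-specific mixture explaining a segment's signal."""

    state1: tuple[int, int]
    state2: tuple[int, int]
    f: float          # tumor-cell fraction in state1
    purity: float
    ploidy: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.f <= 1.0):
            raise ValueError("f must be in [0,1]")
        for na, nb in (self.state1, self.state2):
            if not (na >= nb >= 0):
                raise ValueError("states must satisfy nA >= nB >= 0")
        if not (0.0 < self.purity <= 1.0):
            raise ValueError("purity must be in (0,1]")
        if self.ploidy <= 0:
            raise ValueError("ploidy must be positive")


class ExpectedSignal(NamedTuple):
    baf: float
    logr: float
    baf_folded: float


@dataclass
class LocusMixtureFit:
    """Result of fitting the two-state mixture at a target locus."""

    mixture: StateMixture | None
    f: float
    f_ci: tuple[float, float]
    state2: tuple[int, int]
    objective: float
    clonal: bool
    evaluable: bool
    reason: str = ""


@dataclass(frozen=True)
class PloidyFit:
    """Per-sample purity/ploidy solution with its goodness of fit."""

    sample: str
    purity: float
    ploidy: float
    gof: float  # higher is better


@dataclass
class GeneCall:
    """Per-gene copy-number state call for one sample."""

    gene: str
    sample: str
    state: str              # HomDel | LoH | balanced | gain | mixed
    homdel_fraction: float
    clonal: bool
    segment_logr: float
    deep_deletion: bool


# ---------------------------------------------------------------------------
# Expected signal
# ---------------------------------------------------------------------------

def expected_signal(mix: StateMixture) -> ExpectedSignal:
    """Closed-form (BAF, logR) of a two-state mixture; folded BAF included."""
    rho, psi, f = mix.purity, mix.ploidy, mix.f
    n1a, n1b = mix.state1
    n2a, n2b = mix.state2
    nbar = f * (n1a + n1b) + (1 - f) * (n2a + n2b)
    denom = 2 * (1 - rho) + rho * nbar
    if denom <= 0:
        raise ValueError(
            "degenerate mixture: no DNA present (rho=1 with total copy number 0)"
        )
    baf = ((1 - rho) + rho * (f * n1b + (1 - f) * n2b)) / denom
    norm = 2 * (1 - rho) + rho * psi
    logr = math.log2(denom / norm)
    return ExpectedSignal(baf=baf, logr=logr, baf_folded=max(baf, 1 - baf))


# ---------------------------------------------------------------------------
# Multi-sample segmentation (penalized least squares, exact DP)
# ---------------------------------------------------------------------------

@dataclass
class SegmentationResult:
    breakpoints: list[int]          # indices b: a new segment starts at bin b
    segments: list[tuple[int, int]]  # [start, end] inclusive bin indices
    means: pd.DataFrame             # sample, channel, segment, mean (raw scale)
    objective: float                # penalized objective on standardized data


def _winsorize(x: np.ndarray, n_mad: float = 3.0) -> np.ndarray:
    med = np.median(x)
    mad = np.median(np.abs(x - med)) * 1.4826
    if mad == 0:
        return x.copy()
    return np.clip(x, med - n_mad * mad, med + n_mad * mad)


def multisample_pcf(
    tracks: Sequence[SegmentTrack],
    penalty: float = 15.0,
    fold_baf: bool = True,
) -> SegmentationResult:
    """Joint segmentation of BAF and logR across samples with shared breakpoints.

    Bins are winsorized at 3 MAD and each channel (sample x {baf, logr})
    standardized to unit variance; the exact dynamic-programming minimizer of

        sum over channels of within-segment squared error
        + penalty * (number of breakpoints)

    is returned, with per-sample per-channel segment means on the raw scale.
    BAF is folded to max(b, 1-b) before segmentation by default, matching the
    phased-BAF convention where only the deviation from 0.5 is informative.
    """
    if not tracks:
        raise ValueError("no tracks given")
    grid = tracks[0].bins[["contig", "start", "end"]].reset_index(drop=True)
    for t in tracks[1:]:
        other = t.bins[["contig", "start", "end"]].reset_index(drop=True)
        if not grid.equals(other):
            raise ValueError("all tracks must share an identical bin grid")
    n = len(grid)

    channels: list[tuple[str, str, np.ndarray]] = []
    for t in tracks:
        baf = t.bins["baf"].to_numpy(dtype=float)
        if fold_baf:
            baf = np.maximum(baf, 1.0 - baf)
        for name, values in (("baf", baf), ("logr", t.bins["logr"].to_numpy(dtype=float))):
            channels.append((t.sample, name, values))

    raw = np.vstack([v for _, _, v in channels])           # (C, n)
    wins = np.vstack([_winsorize(v) for _, _, v in channels])
    sd = wins.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    std = (wins - wins.mean(axis=1, keepdims=True)) / sd[:, None]

    # prefix sums for O(1) multi-channel segment cost
    c1 = np.concatenate([np.zeros((std.shape[0], 1)), np.cumsum(std, axis=1)], axis=1)
    c2 = np.concatenate([np.zeros((std.shape[0], 1)), np.cumsum(std**2, axis=1)], axis=1)

    def seg_cost(i: int, j: int) -> float:
        """Summed within-segment SSE over channels for bins i..j inclusive."""
        m = j - i + 1
        s = c1[:, j + 1] - c1[:, i]
        q = c2[:, j + 1] - c2[:, i]
        return float(np.sum(q - s * s / m))

    best = np.full(n + 1, np.inf)
    best[0] = -penalty  # first segment carries no breakpoint penalty
    back = np.zeros(n + 1, dtype=int)
    for j in range(1, n + 1):
        for i in range(j):
            cand = best[i] + penalty + seg_cost(i, j - 1)
            if cand < best[j]:
                best[j] = cand
                back[j] = i
    segments: list[tuple[int, int]] = []
    j = n
    while j > 0:
        i = back[j]
        segments.append((i, j - 1))
        j = i
    segments.reverse()
    breakpoints = [s for s, _ in segments[1:]]

    rows = []
    for k, (i, j) in enumerate(segments):
        for (sample, channel, _), vals in zip(channels, raw):
            rows.append(
                {"sample": sample, "channel": channel, "segment": k,
                 "start_bin": i, "end_bin": j, "mean": float(vals[i : j + 1].mean())}
            )
    return SegmentationResult(
        breakpoints=breakpoints,
        segments=segments,
        means=pd.DataFrame(rows),
        objective=float(best[n]),
    )


# ---------------------------------------------------------------------------
# Mixture fitting
# ---------------------------------------------------------------------------

def baf_band_deviation(baf: np.ndarray, n_iter: int = 60) -> tuple[float, float]:
    """(delta, sigma) of the symmetric BAF band mixture around 0.5.

    Phased germline BAF in a segment splits into two bands 0.5 +/- delta with
    per-bin noise sigma. Folding the bins and averaging overstates delta when
    it is small relative to sigma (the folded-noise bias), so delta is instead
    estimated by EM on the equal-weight two-component Gaussian mixture
    {N(0.5+delta, sigma), N(0.5-delta, sigma)}.
    """
    x = np.asarray(baf, dtype=float) - 0.5
    sd = float(x.std(ddof=0)) or 1e-4
    delta = 0.8 * sd
    sigma = max(0.6 * sd, 1e-4)
    for _ in range(n_iter):
        # responsibility of the +delta band
        d_plus = (x - delta) ** 2
        d_minus = (x + delta) ** 2
        z = np.clip((d_minus - d_plus) / (2 * sigma**2), -700, 700)
        r = 1.0 / (1.0 + np.exp(-z))
        delta_new = float(np.sum(r * x - (1 - r) * x) / len(x))
        delta_new = max(delta_new, 0.0)
        var = float(np.mean(r * (x - delta_new) ** 2 + (1 - r) * (x + delta_new) ** 2))
        sigma_new = max(math.sqrt(max(var, 0.0)), 1e-4)
        if abs(delta_new - delta) < 1e-10 and abs(sigma_new - sigma) < 1e-10:
            delta, sigma = delta_new, sigma_new
            break
        delta, sigma = delta_new, sigma_new
    return delta, sigma


def _state2_grid(max_cn: int) -> list[tuple[int, int]]:
    return [
        (na, nb)
        for na in range(max_cn + 1)
        for nb in range(na + 1)
        if na + nb <= max_cn
    ]


def _best_f_for_state(
    obs_baf: float, obs_logr: float, state2: tuple[int, int], purity: float, ploidy: float
) -> tuple[float, float]:
    """(f, objective) minimizing squared (folded BAF, logR) distance for one state2."""
    from scipy.optimize import minimize_scalar

    def objective(f: float) -> float:
        try:
            sig = expected_signal(
                StateMixture((0, 0), state2, f, purity, ploidy)
            )
        except ValueError:
            return np.inf
        return (sig.baf_folded - obs_baf) ** 2 + (sig.logr - obs_logr) ** 2

    grid = np.linspace(0.0, 1.0, 101)
    vals = np.array([objective(f) for f in grid])
    k = int(np.argmin(vals))
    lo, hi = grid[max(0, k - 1)], grid[min(100, k + 1)]
    res = minimize_scalar(objective, bounds=(lo, hi), method="bounded")
    if res.fun <= vals[k]:
        return float(res.x), float(res.fun)
    return float(grid[k]), float(vals[k])


def fit_locus_mixture(
    baf_bins: np.ndarray,
    logr_bins: np.ndarray,
    purity: float,
    ploidy: float,
    max_cn: int = 4,
    n_boot: int = 100,
    seed: int = 0,
    min_purity: float = 0.10,
) -> LocusMixtureFit:
    """Fit the HomDel-vs-background mixture fraction at a target locus segment.

    State 1 is fixed to the homozygous deletion (0,0); state 2 ranges over all
    allele-specific states with total copy number <= ``max_cn``. The mixture
    fraction minimizing the squared distance between the model's (folded BAF,
    logR) and the observed segment means is found per state and the best state
    kept, breaking near-ties (observationally equivalent states) toward the
    smallest total copy number. Confidence intervals come from resampling bins
    within the segment. Samples at purity <= ``min_purity`` are marked
    non-evaluable, mirroring the >10% tumor-fraction inclusion rule for
    cfDNA copy-number analysis.
    """
    baf_bins = np.asarray(baf_bins, dtype=float)
    logr_bins = np.asarray(logr_bins, dtype=float)
    if purity <= min_purity:
        return LocusMixtureFit(
            mixture=None, f=np.nan, f_ci=(np.nan, np.nan), state2=(0, 0),
            objective=np.nan, clonal=False, evaluable=False,
            reason=f"purity {purity:.3f} <= {min_purity:.2f}",
        )

    def fit_once(baf: np.ndarray, logr: np.ndarray) -> tuple[float, tuple[int, int], float]:
        delta, _ = baf_band_deviation(baf)
        obs_baf = 0.5 + delta
        obs_logr = float(np.mean(logr))
        results = []
        for state2 in _state2_grid(max_cn):
            f, obj = _best_f_for_state(obs_baf, obs_logr, state2, purity, ploidy)
            results.append((obj, sum(state2), state2, f))
        # states with all-equal or all-A alleles are observationally equivalent
        # along shared (n_bar, BAF) manifolds; a small complexity penalty keeps
        # noise at the f-range boundary from promoting a higher-copy equivalent
        lam = 1e-3
        results.sort(key=lambda r: (r[0] + lam * r[1], r[1], r[2]))
        obj, _, state2, f = results[0]
        if state2 == (0, 0):
            f = 1.0  # both states homozygously deleted: the mixture is pure HomDel
        return f, state2, obj

    f_hat, state2, obj = fit_once(baf_bins, logr_bins)
    rng = np.random.default_rng(seed)
    n = len(baf_bins)
    boots = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        fb, _, _ = fit_once(baf_bins[idx], logr_bins[idx])
        boots.append(fb)
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))) if boots else (f_hat, f_hat)
    mixture = StateMixture((0, 0), state2, f_hat, purity, ploidy)
    return LocusMixtureFit(
        mixture=mixture,
        f=f_hat,
        f_ci=ci,
        state2=state2,
        objective=obj,
        clonal=(f_hat >= CLONAL_MIN_F or f_hat <= 1 - CLONAL_MIN_F),
        evaluable=True,
    )


# ---------------------------------------------------------------------------
# Purity/ploidy estimation and reconciliation
# ---------------------------------------------------------------------------

def estimate_purity_ploidy(
    track: SegmentTrack,
    purity_grid: np.ndarray | None = None,
    ploidy_grid: np.ndarray | None = None,
    penalty: float = 15.0,
) -> PloidyFit:
    """Grid-search purity/ploidy from how well segment means hit integer states.

    The track is segmented, then each (rho, psi) candidate is scored by the
    distance of every segment's (folded BAF, logR) mean to its best integer
    allele-specific state (total copy number <= 6); goodness of fit is
    1/(1 + length-weighted mean squared distance).
    """
    if purity_grid is None:
        purity_grid = np.arange(0.15, 1.0001, 0.05)
    if ploidy_grid is None:
        ploidy_grid = np.arange(1.2, 5.2001, 0.1)
    seg = multisample_pcf([track], penalty=penalty)
    means = seg.means
    states = _state2_grid(6)
    seg_stats = []
    for k, (i, j) in enumerate(seg.segments):
        m = means[means["segment"] == k]
        baf = float(m[m["channel"] == "baf"]["mean"].iloc[0])
        logr = float(m[m["channel"] == "logr"]["mean"].iloc[0])
        seg_stats.append((baf, logr, j - i + 1))
    total_bins = sum(w for _, _, w in seg_stats)

    best: PloidyFit | None = None
    for rho in purity_grid:
        for psi in ploidy_grid:
            err = 0.0
            for baf, logr, w in seg_stats:
                d = min(
                    (expected_signal(StateMixture((0, 0), s, 0.0, rho, psi)).baf_folded - baf) ** 2
                    + (expected_signal(StateMixture((0, 0), s, 0.0, rho, psi)).logr - logr) ** 2
                    for s in states
                )
                err += w * d
            gof = 1.0 / (1.0 + err / total_bins)
            if best is None or gof > best.gof:
                best = PloidyFit(track.sample, float(rho), float(psi), float(gof))
    assert best is not None
    return best


def reconcile_ploidy(
    fits: Sequence[PloidyFit],
    refit: Callable[[PloidyFit, tuple[float, float]], PloidyFit],
    window: float = 0.6,
) -> list[PloidyFit]:
    """Harmonize per-sample ploidy solutions within a patient.

    If all rounded ploidies agree the fits are returned unchanged. Otherwise
    the sample(s) with lower goodness of fit are re-fitted (via ``refit``,
    which receives the fit and a (lo, hi) ploidy window) over a +/- ``window``
    interval centered on the best-GoF sample's ploidy, and the best re-fit is
    adopted.
    """
    if len(fits) < 2:
        raise ValueError("need at least 2 samples per patient")
    for f in fits:
        if f.gof is None or not math.isfinite(f.gof):
            raise ValueError(f"missing goodness of fit for sample {f.sample}")
    rounded = {round(f.ploidy) for f in fits}
    if len(rounded) == 1:
        return list(fits)
    anchor = max(fits, key=lambda f: f.gof)
    out = []
    for f in fits:
        if f.sample == anchor.sample:
            out.append(f)
        else:
            out.append(refit(f, (anchor.ploidy - window, anchor.ploidy + window)))
    return out


# ---------------------------------------------------------------------------
# Gene intersection
# ---------------------------------------------------------------------------

def _state_label(fit: LocusMixtureFit) -> str:
    if not fit.evaluable:
        return "non-evaluable"
    if fit.f >= CLONAL_MIN_F:
        return "HomDel"
    if fit.f > 1 - CLONAL_MIN_F:
        return "mixed"
    na, nb = fit.state2
    if (na, nb) == (0, 0):
        return "HomDel"
    if nb == 0 or (na != nb and na + nb <= 2):
        return "LoH"
    if (na, nb) == (1, 1):
        return "balanced"
    return "gain"


def genes_overlap(
    segments: pd.DataFrame,
    gene_table: pd.DataFrame,
) -> list[GeneCall]:
    """Per-gene state calls by majority-overlap segment intersection.

    ``segments`` columns: sample, contig, start, end (1-based inclusive),
    state, homdel_fraction, clonal, logr. ``gene_table`` columns follow BED:
    contig, start, end (0-based half-open), gene; converted to 1-based
    inclusive at this boundary. Each gene takes the state of the overlapping
    segment covering the majority of its span; segments with logR below -2 are
    flagged as deep deletions. A gene with no overlapping segment raises.
    """
    calls: list[GeneCall] = []
    for _, g in gene_table.iterrows():
        g_start = int(g["start"]) + 1  # BED 0-based half-open -> 1-based inclusive
        g_end = int(g["end"])
        for sample, segs in segments.groupby("sample"):
            overlaps = []
            for _, s in segs.iterrows():
                if s["contig"] != g["contig"]:
                    continue
                ov = min(g_end, int(s["end"])) - max(g_start, int(s["start"])) + 1
                if ov > 0:
                    overlaps.append((ov, s))
            if not overlaps:
                raise ValueError(
                    f"gene {g['gene']} has no overlapping segment in sample {sample}"
                )
            overlaps.sort(key=lambda t: -t[0])
            _, seg = overlaps[0]
            logr = float(seg["logr"])
            calls.append(
                GeneCall(
                    gene=str(g["gene"]),
                    sample=str(sample),
                    state=str(seg["state"]),
                    homdel_fraction=float(seg["homdel_fraction"]),
                    clonal=bool(seg["clonal"]),
                    segment_logr=logr,
                    deep_deletion=logr < DEEP_DELETION_LOGR,
                )
            )
    return calls
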