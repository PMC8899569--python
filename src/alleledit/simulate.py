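"""Synthetic data generators with known ground truth.

Four generators emulate the study's data streams:

* amplicon FASTQ reads from a heterozygous two-allele locus, with Cas9 indels
  at the guide cut site and substitution sequencing errors;
* mouse cohorts with per-animal editing efficacy and ABR thresholds linked by
  a linear dose-response plus Gaussian noise;
* T7E1 gel densitometry (the forward model of the variant-frequency formula);
* FluxOR fluorescence traces, as tables or as image stacks with ROI masks.

Every generator takes an explicit integer seed and is fully reproducible:
identical seeds give byte-identical output.  Truth tables carry one row per
simulated record.
"""

from __future__ import annotations

import gzip
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fluxor import FluxTrace
from .guides import GuideCandidate, cut_site
from .reference import AmpliconReference, derive_wt_sequence
from .t7e1 import expected_fraction_cleaved

BASES = np.array(list("ACGT"))
READ_QUALITY_CHAR = "F"  # constant Phred Q37; no quality filtering is modelled

#: Generic Cas9 NHEJ-like indel length spectrum: dominated by +/-1, with a
#: deletion-heavy tail that includes in-frame lengths and a small >8 bp tail,
#: so that classifier exclusion rules are exercised by default.
DEFAULT_INDEL_WEIGHTS: dict[int, float] = {
    1: 0.30, -1: 0.25, -2: 0.10, 2: 0.04, -3: 0.07, 3: 0.02, -4: 0.05,
    -5: 0.04, -6: 0.03, -7: 0.03, -8: 0.02, -9: 0.02, -10: 0.02, -12: 0.01,
}


# ---------------------------------------------------------------------------
# FASTQ read simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimConfig:
    """Amplicon read simulation parameters.

    ``editing_rate_mutant`` / ``editing_rate_wt`` are per-allele probabilities
    that a read carries exactly one cut-site indel, its signed length drawn
    from ``indel_length_weights`` (negative = deletion).  Substitution errors
    are applied uniformly per base after editing.
    """

    n_reads: int
    editing_rate_mutant: float = 0.0
    editing_rate_wt: float = 0.0
    read_length: int = 150
    allele_fraction_mutant: float = 0.5
    indel_length_weights: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_WEIGHTS))
    substitution_error_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be positive")
        for name in ("editing_rate_mutant", "editing_rate_wt",
                     "allele_fraction_mutant", "substitution_error_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        w = dict(self.indel_length_weights)
        object.__setattr__(self, "indel_length_weights", w)
        if any(wt < 0 for wt in w.values()):
            raise ValueError("indel length weights must be nonnegative")
        if any(not isinstance(k, int) or k == 0 for k in w):
            raise ValueError("indel lengths must be nonzero signed integers")
        editing = max(self.editing_rate_mutant, self.editing_rate_wt)
        if editing > 0 and sum(w.values()) == 0:
            raise ValueError("editing requested but indel weights are all zero")


def _apply_indel(seq: str, cut0: int, length: int, rng: np.random.Generator) -> str:
    """One indel whose left breakpoint is the cut (0-based between-base cut0)."""
    if length < 0:
        k = -length
        if cut0 + k > len(seq):
            raise ValueError("deletion extends beyond the amplicon")
        return seq[:cut0] + seq[cut0 + k:]
    ins = "".join(rng.choice(BASES, size=length))
    return seq[:cut0] + ins + seq[cut0:]


def simulate_reads(ref: AmpliconReference, guide: GuideCandidate | int,
                   cfg: ReadSimConfig
                   ) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Simulate amplicon reads from a heterozygous two-allele locus.

    Returns ``(records, truth)`` where records are ``(id, sequence, quality)``
    tuples (constant Q37 qualities) and truth has one row per read:
    allele, edited flag, signed indel length, indel position, error count.

    Each read is drawn from the mutant or wild-type allele, optionally edited
    with exactly one cut-site indel, then start-positioned uniformly among
    windows that cover both the marker and the cut-site neighbourhood
    (so downstream classification is never coverage-limited).
    """
    rng = np.random.default_rng(cfg.seed)
    cut = cut_site(guide) if isinstance(guide, GuideCandidate) else int(guide)
    marker = ref.marker_site
    if marker is None:
        raise ValueError("reference needs a marker site to simulate allele reads")
    mut_seq = ref.sequence
    wt_seq = derive_wt_sequence(ref)
    marker0 = marker.offset - 1
    cut0 = cut  # 0-based between-base index of the 1-based cut offset
    margin = 10

    lengths = np.array(sorted(cfg.indel_length_weights), dtype=int)
    probs = np.array([cfg.indel_length_weights[k] for k in lengths], dtype=float)
    probs = probs / probs.sum() if probs.sum() > 0 else probs

    is_mutant = rng.random(cfg.n_reads) < cfg.allele_fraction_mutant
    u_edit = rng.random(cfg.n_reads)

    records: list[tuple[str, str, str]] = []
    rows = []
    for i in range(cfg.n_reads):
        mutant = bool(is_mutant[i])
        allele_seq = mut_seq if mutant else wt_seq
        rate = cfg.editing_rate_mutant if mutant else cfg.editing_rate_wt
        edited = bool(u_edit[i] < rate)
        indel_len = 0
        seq = allele_seq
        if edited:
            indel_len = int(rng.choice(lengths, p=probs))
            seq = _apply_indel(seq, cut0, indel_len, rng)
        # coverage requirements in edited coordinates
        lo = min(marker0, cut0 - margin)
        hi = max(marker0, cut0 + margin + max(indel_len, 0))
        L = min(cfg.read_length, len(seq))
        s_min = max(0, hi + 1 - L)
        s_max = min(lo, len(seq) - L)
        if s_min > s_max:
            raise ValueError(
                "read_length too short to cover both the marker and the "
                "cut-site window")
        start = int(rng.integers(s_min, s_max + 1))
        read = seq[start:start + L]
        n_err = int(rng.binomial(L, cfg.substitution_error_rate)) \
            if cfg.substitution_error_rate > 0 else 0
        if n_err:
            pos = rng.choice(L, size=n_err, replace=False)
            arr = list(read)
            for p in pos:
                choices = [b for b in "ACGT" if b != arr[p]]
                arr[p] = choices[int(rng.integers(3))]
            read = "".join(arr)
        rid = f"read_{i:06d}"
        records.append((rid, read, READ_QUALITY_CHAR * L))
        rows.append({
            "read_id": rid,
            "allele": "mutant" if mutant else "wt",
            "edited": edited,
            "indel_len": indel_len,
            "indel_ref_offset": cut if edited else pd.NA,
            "n_subst_errors": n_err,
            "start0": start,
        })
    return records, pd.DataFrame(rows)


def expected_read_class(allele: str, edited: bool, indel_len: int,
                        min_len: int = 1, max_len: int = 8) -> str:
    """Ground-truth read class implied by a truth-table row."""
    if allele == "wt":
        return "wt"
    if not edited:
        return "mutant_unedited"
    if indel_len != 0 and min_len <= abs(indel_len) <= max_len \
            and indel_len % 3 != 0:
        return "mutant_edited"
    return "mutant_excluded"


def write_fastq(records: Sequence[tuple[str, str, str]], path: str | Path) -> None:
    """Write 4-line FASTQ records; gzip-compressed when the path ends in .gz."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as fh:
        for rid, seq, qual in records:
            fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")


def read_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Iterate (read_id, sequence) pairs from a FASTQ file (.gz supported)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline().strip()
            fh.readline()
            fh.readline()
            yield header.strip().lstrip("@").split()[0], seq


# ---------------------------------------------------------------------------
# Mouse cohort simulation (efficacy -> ABR improvement)
# ---------------------------------------------------------------------------

DEFAULT_BASELINES_DB: dict[float, float] = {6.0: 55.0, 12.0: 60.0, 18.0: 65.0,
                                            24.0: 70.0, 30.0: 75.0}


@dataclass(frozen=True)
class CohortSimConfig:
    """Linear-plus-noise model linking editing efficacy to hearing improvement.

    Per mouse: efficacy ~ Normal(mean, sd) truncated at 0; injected-ear
    threshold per frequency = baseline - db_per_percent x efficacy + noise;
    contralateral ear = baseline + independent noise.  Thresholds are clipped
    to the instrument range [10, 95] dB SPL.
    """

    n_mice: int
    efficacy_mean: float = 5.0
    efficacy_sd: float = 2.0
    db_per_percent: float = 1.0
    noise_sd_db: float = 3.0
    frequencies: tuple[float, ...] = (6.0, 12.0, 18.0, 24.0, 30.0)
    baseline_thresholds: Mapping[float, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINES_DB))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mice < 3:
            raise ValueError("n_mice must be >= 3 (correlation needs 3 points)")
        if self.efficacy_sd < 0 or self.noise_sd_db < 0:
            raise ValueError("standard deviations must be nonnegative")
        missing = [f for f in self.frequencies
                   if float(f) not in {float(k) for k in self.baseline_thresholds}]
        if missing:
            raise ValueError(f"no baseline threshold for frequencies {missing}")


def simulate_cohort(cfg: CohortSimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort; returns (mouse table, truth table).

    The mouse table is wide (one row per animal) with ``inj_<f>kHz`` /
    ``con_<f>kHz`` threshold columns and the true efficacy as the measured
    ``efficacy_percent``.  Truth carries the true efficacy and the true mean
    shift ``db_per_percent * efficacy``.  With ``efficacy_sd = 0`` the table
    is still valid but the sample correlation is undefined (flagged column
    ``degenerate_efficacy``).
    """
    rng = np.random.default_rng(cfg.seed)
    if cfg.efficacy_sd == 0:
        eff = np.full(cfg.n_mice, float(cfg.efficacy_mean))
    else:
        a = (0.0 - cfg.efficacy_mean) / cfg.efficacy_sd
        eff = stats.truncnorm.rvs(a, np.inf, loc=cfg.efficacy_mean,
                                  scale=cfg.efficacy_sd, size=cfg.n_mice,
                                  random_state=rng)
    rows, truth_rows = [], []
    degenerate = bool(cfg.efficacy_sd == 0)
    for i in range(cfg.n_mice):
        mid = f"mouse_{i:03d}"
        row = {"mouse_id": mid, "treatment": "injected",
               "efficacy_percent": float(eff[i]),
               "degenerate_efficacy": degenerate}
        for f in cfg.frequencies:
            base = float(dict((float(k), v) for k, v in
                              cfg.baseline_thresholds.items())[float(f)])
            label = int(f) if float(f).is_integer() else f
            inj = base - cfg.db_per_percent * eff[i] \
                + rng.normal(0.0, cfg.noise_sd_db)
            con = base + rng.normal(0.0, cfg.noise_sd_db)
            row[f"inj_{label}kHz"] = float(np.clip(inj, 10.0, 95.0))
            row[f"con_{label}kHz"] = float(np.clip(con, 10.0, 95.0))
        rows.append(row)
        truth_rows.append({"mouse_id": mid, "true_efficacy": float(eff[i]),
                           "true_mean_shift": float(cfg.db_per_percent * eff[i])})
    return pd.DataFrame(rows), pd.DataFrame(truth_rows)


def population_correlation(db_per_percent: float, efficacy_sd: float,
                           noise_sd_db: float, n_frequencies: int = 5) -> float:
    """Closed-form population Pearson r of (efficacy, mean shift).

    mean shift = s*e + eps with eps the mean over m frequencies of the
    difference of two independent Gaussian noises, Var(eps) = 2*tau^2/m, so
    r = s*sigma / sqrt(s^2 sigma^2 + 2 tau^2 / m).
    """
    s2 = (db_per_percent * efficacy_sd) ** 2
    return math.copysign(
        math.sqrt(s2 / (s2 + 2.0 * noise_sd_db ** 2 / n_frequencies)),
        db_per_percent)


def noise_sd_for_target_correlation(target_r: float, db_per_percent: float,
                                    efficacy_sd: float,
                                    n_frequencies: int = 5) -> float:
    """Per-frequency, per-ear threshold noise sd giving population r = target.

    Inverts :func:`population_correlation`:
    tau = |s| * sigma * sqrt(m (1 - r^2) / (2 r^2)).
    """
    if not (0.0 < target_r < 1.0):
        raise ValueError("target_r must lie strictly in (0, 1)")
    return (abs(db_per_percent) * efficacy_sd
            * math.sqrt(n_frequencies * (1.0 - target_r ** 2)
                        / (2.0 * target_r ** 2)))


# ---------------------------------------------------------------------------
# T7E1 densitometry forward model
# ---------------------------------------------------------------------------

def simulate_t7e1(true_frequency_percent: float, density_noise_sd: float = 0.0,
                  seed: int | np.random.Generator | None = None
                  ) -> tuple[float, float]:
    """Noisy (cleaved, uncut) relative densities for a true variant frequency.

    Noiseless cleaved fraction f = 1 - (1 - p/100)^2; densities sum to 1,
    are perturbed with Gaussian noise and clipped at zero.
    """
    f = expected_fraction_cleaved(true_frequency_percent)
    cleaved, uncut = f, 1.0 - f
    if density_noise_sd > 0:
        rng = (seed if isinstance(seed, np.random.Generator)
               else np.random.default_rng(seed))
        cleaved = max(0.0, cleaved + rng.normal(0.0, density_noise_sd))
        uncut = max(0.0, uncut + rng.normal(0.0, density_noise_sd))
    return float(cleaved), float(uncut)


# ---------------------------------------------------------------------------
# FluxOR trace / image-stack simulation
# ---------------------------------------------------------------------------

DEFAULT_SLOPES: dict[str, float] = {
    "WT": 0.5, "AAV_injected": 0.3, "non_injected": 0.05,
}


@dataclass(frozen=True)
class FluxSimConfig:
    """Linear thallium-influx trace model F(t) = F0 + slope*t + noise.

    ``slope_by_group`` assigns one influx slope (fluorescence units per
    second) per experimental group; slopes may be zero (inhibitor controls).
    """

    n_rois: int = 6
    f0_mean: float = 100.0
    f0_sd: float = 5.0
    slope_by_group: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_SLOPES))
    noise_sd: float = 0.0
    frame_interval_s: float = 2.0
    duration_s: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rois < 1:
            raise ValueError("need at least one ROI")
        if self.duration_s < self.frame_interval_s:
            raise ValueError("duration must cover at least one frame interval")
        if not self.slope_by_group:
            raise ValueError("slope_by_group must name at least one group")
        object.__setattr__(self, "slope_by_group", dict(self.slope_by_group))


def simulate_flux(cfg: FluxSimConfig) -> tuple[list[FluxTrace], pd.DataFrame]:
    """Simulate per-ROI traces; returns (traces, truth).

    ROIs are assigned to groups round-robin over ``slope_by_group`` (sorted
    group order, deterministic).  Truth has one row per ROI with the true F0
    and slope.
    """
    rng = np.random.default_rng(cfg.seed)
    t = np.arange(0.0, cfg.duration_s + cfg.frame_interval_s / 2,
                  cfg.frame_interval_s)
    groups = sorted(cfg.slope_by_group)
    traces, rows = [], []
    for i in range(cfg.n_rois):
        group = groups[i % len(groups)]
        slope = float(cfg.slope_by_group[group])
        f0 = float(rng.normal(cfg.f0_mean, cfg.f0_sd)) if cfg.f0_sd > 0 \
            else cfg.f0_mean
        f = f0 + slope * t
        if cfg.noise_sd > 0:
            f = f + rng.normal(0.0, cfg.noise_sd, size=t.size)
        roi = f"roi_{i:03d}"
        traces.append(FluxTrace(roi_id=roi, group=group, t=t, f=f))
        rows.append({"roi_id": roi, "group": group,
                     "true_f0": f0, "true_slope": slope})
    return traces, pd.DataFrame(rows)


def make_roi_grid(n_rois: int, roi_shape: tuple[int, int] = (8, 8),
                  gap: int = 2) -> tuple[dict[str, np.ndarray], tuple[int, int]]:
    """Disjoint rectangular ROI masks laid out on a grid.

    Returns (masks, frame_shape).  The grid construction guarantees the ROIs
    are pairwise disjoint; a zero or negative gap would overlap them and is
    rejected.
    """
    if gap < 1:
        raise ValueError("ROI gap must be >= 1 pixel (ROIs must not overlap)")
    h, w = roi_shape
    ncol = int(math.ceil(math.sqrt(n_rois)))
    nrow = int(math.ceil(n_rois / ncol))
    frame = (nrow * (h + gap) + gap, ncol * (w + gap) + gap)
    masks: dict[str, np.ndarray] = {}
    for i in range(n_rois):
        r, c = divmod(i, ncol)
        mask = np.zeros(frame, dtype=bool)
        y0 = gap + r * (h + gap)
        x0 = gap + c * (w + gap)
        mask[y0:y0 + h, x0:x0 + w] = True
        masks[f"roi_{i:03d}"] = mask
    return masks, frame


def simulate_flux_stack(cfg: FluxSimConfig, roi_shape: tuple[int, int] = (8, 8)
                        ) -> tuple[np.ndarray, dict[str, np.ndarray],
                                   dict[str, str], pd.DataFrame]:
    """Image-stack variant: (stack, roi_masks, roi_groups, truth).

    Every pixel of an ROI carries the trace value for that frame, so ROI
    pixel means reproduce the simulated traces exactly; background is zero.
    """
    traces, truth = simulate_flux(cfg)
    masks, frame = make_roi_grid(cfg.n_rois, roi_shape)
    n_frames = traces[0].t.size
    stack = np.zeros((n_frames, *frame), dtype=float)
    groups = {}
    for tr in traces:
        mask = masks[tr.roi_id]
        stack[:, mask] = tr.f[:, None]
        groups[tr.roi_id] = tr.group
    return stack, masks, groups, truth
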