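"""Synthetic study generator: audio, annotations, phenotypes, playback logs,
and microsatellite genotypes with known ground truth.

The generator emulates a two-season nest-box study of a trilling songbird:

* **Song.**  Each male carries latent singing abilities for vocal deviation
  and trill consistency (Gaussian male effects on top of within-male
  trill-to-trill noise, giving a configurable repeatability
  ``var_between / (var_between + var_within)``).  Per-trill (rate,
  bandwidth) points are placed strictly under a linear performance limit
  ``B = a_true * T + b_true``, producing the band/triangle-shaped cloud
  characteristic of trill performance data.
* **Audio.**  Trills are sequences of linear FM sweeps with raised-cosine
  (Tukey) amplitude envelopes plus white Gaussian background noise at a
  configurable SNR.  Consistency is controlled by a single knob: a
  multiplicative Gaussian jitter on sweep endpoints and duration.  Audio is
  rendered lazily, one male-year at a time, from per-male-year child seeds,
  so bundles are deterministic without holding waveforms in memory.
* **Paternity.**  Offspring genotypes are Mendelian draws from their true
  parents over 7 microsatellite loci with realistic allele counts,
  locus-specific null-allele frequencies (a hidden allele that makes
  heterozygotes appear homozygous), and single-step mutation.  A configurable
  fraction of offspring is sired by a non-social male.
* **Phenotype & behavior.**  Morphometrics, capture dates/times, immune
  indices, banding histories, and playback event logs (song events,
  song-bout windows, within-5-m position intervals, speaker crossings).

Defaults mirror the observed study conditions: 60 males over two seasons
(a subset recorded in both), ~60 trills per male-year, extra-pair rate
0.135, and null-allele frequencies from the published locus panel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile
from scipy.signal.windows import hann, tukey

__all__ = [
    "SyllableSpec",
    "TrillGroundTruth",
    "PopulationConfig",
    "StudyBundle",
    "synth_syllable",
    "synth_trill",
    "simulate_trill_cloud",
    "simulate_population",
    "load_bundle",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class SyllableSpec:
    """One frequency sweep: start/end frequency (Hz), duration (s), envelope."""

    f_start: float
    f_end: float
    duration: float
    amplitude_envelope: str = "raised_cosine"  # raised_cosine | hann | flat
    sweep_shape: str = "linear"  # linear | exponential

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("syllable duration must be positive")
        if self.f_start <= 0 or self.f_end <= 0:
            raise ValueError("sweep frequencies must be positive")


@dataclass
class TrillGroundTruth:
    """Latent truth for one trill, sufficient to render and to score recovery."""

    male_id: str
    year: int
    trill_type: int
    rate: float  # syllables / s
    bandwidth: float  # Hz (target 99%-energy bandwidth)
    pitch: float  # Hz (high frequency of the sweeps)
    jitter_sd: float  # multiplicative jitter controlling consistency
    n_syllables: int
    time_in_song: float

    def __post_init__(self) -> None:
        if self.n_syllables < 2:
            raise ValueError("a trill has at least 2 syllables")


def _as_trait_map(value, default_map):
    if isinstance(value, dict):
        out = dict(default_map)
        out.update(value)
        return out
    return {k: float(value) for k in default_map}


# locus panel emulating a 7-marker microsatellite set: allele counts and
# null-allele frequencies follow the published descriptive statistics
_DEFAULT_N_ALLELES = (12, 10, 18, 17, 28, 7, 17)
_DEFAULT_NULL_FREQ = (0.0, 0.059, 0.054, 0.0, 0.0, 0.063, 0.0)


def _geometric_freqs(k: int, decay: float = 0.82) -> np.ndarray:
    w = decay ** np.arange(k)
    return w / w.sum()


@dataclass
class PopulationConfig:
    """Study-design knobs for :func:`simulate_population`.

    The defaults are the study conditions the package is validated under:
    a null world (no song -> success effects), repeatabilities on the order
    seen in trill data, extra-pair rate 0.135, simultaneous polygyny ~0.2.
    """

    n_males: int = 60
    years: tuple[int, ...] = (2009, 2010)
    n_both_years: int = 14  # males recorded in both seasons
    trills_per_male: tuple[int, int] = (40, 80)
    a_true: float = -168.50  # Hz per (syll/s)
    b_true: float = 6019.0  # Hz
    # variance of the male effect / residual on each latent trait scale;
    # repeatability target = var_between / (var_between + var_within)
    var_between: object = field(
        default_factory=lambda: {"deviation": 0.176, "consistency": 0.295}
    )
    var_within: object = field(
        default_factory=lambda: {"deviation": 0.824, "consistency": 0.705}
    )
    # map trait -> outcome -> slope on the standardized male latent trait in
    # the outcome's linear predictor; default empty = the null world
    effect_sizes: dict = field(default_factory=dict)
    n_loci: int = 7
    allele_freqs: list | None = None  # per locus; default geometric panels
    null_allele_freq: list | None = None
    mutation_rate: float = 0.001  # per transmitted allele
    ep_rate: float = 0.135  # proportion of offspring extra-pair
    polygyny_rate: float = 0.21
    mean_brood: float = 4.5
    deviation_mean: float = 8.2  # orthogonal-distance units
    deviation_sd: float = 3.0
    deviation_distribution: str = "gaussian"  # gaussian | exponential
    consistency_mean: float = 1.7  # on the -log(1 - C) scale
    consistency_sd: float = 0.4
    n_types: int = 8
    snr_db: float = 30.0
    sample_rate: int = 48000
    measurement_noise_bandwidth: float = 30.0  # Hz, tabular mode
    measurement_noise_consistency: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("ep_rate", "polygyny_rate", "mutation_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        self.var_between = _as_trait_map(
            self.var_between, {"deviation": 0.176, "consistency": 0.295}
        )
        self.var_within = _as_trait_map(
            self.var_within, {"deviation": 0.824, "consistency": 0.705}
        )
        for m in (self.var_between, self.var_within):
            if any(v < 0 for v in m.values()):
                raise ValueError("variances must be nonnegative")
        if self.allele_freqs is None:
            counts = [
                _DEFAULT_N_ALLELES[i % len(_DEFAULT_N_ALLELES)] for i in range(self.n_loci)
            ]
            self.allele_freqs = [_geometric_freqs(k) for k in counts]
        else:
            self.allele_freqs = [np.asarray(f, float) for f in self.allele_freqs]
            for f in self.allele_freqs:
                if abs(f.sum() - 1.0) > 1e-8:
                    raise ValueError("allele frequency vectors must sum to 1")
        if self.null_allele_freq is None:
            self.null_allele_freq = [
                _DEFAULT_NULL_FREQ[i % len(_DEFAULT_NULL_FREQ)] for i in range(self.n_loci)
            ]
        if len(self.allele_freqs) != self.n_loci or len(self.null_allele_freq) != self.n_loci:
            raise ValueError("allele_freqs / null_allele_freq length must equal n_loci")


# ---------------------------------------------------------------------------
# audio synthesis
# ---------------------------------------------------------------------------


def _envelope(name: str, n: int) -> np.ndarray:
    if name == "raised_cosine":
        return tukey(n, alpha=0.25)
    if name == "hann":
        return hann(n, sym=True)
    if name == "flat":
        return np.ones(n)
    raise ValueError(f"unknown amplitude envelope {name!r}")


def _span_fraction(env: np.ndarray, fraction: float = 0.99) -> float:
    """Fraction of the sweep's frequency span covered by the central
    `fraction` of envelope energy (frequency is linear in time for a linear
    sweep, so energy tails in time are energy tails in frequency)."""
    e = np.cumsum(env**2)
    e /= e[-1]
    tail = (1 - fraction) / 2
    lo = np.searchsorted(e, tail)
    hi = np.searchsorted(e, 1 - tail)
    return max((hi - lo) / env.size, 1e-3)


def span_correction(envelope: str = "raised_cosine", fraction: float = 0.99) -> float:
    """Multiply a target 99%-energy bandwidth by this to get the sweep span."""
    return 1.0 / _span_fraction(_envelope(envelope, 4096), fraction)


def synth_syllable(
    spec: SyllableSpec,
    sample_rate: float,
    jitter_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one frequency sweep.

    With ``jitter_sd > 0`` the start/end frequencies and the duration are
    each perturbed multiplicatively by ``1 + N(0, jitter_sd)`` draws from
    ``rng`` — the single knob through which trill consistency is degraded.
    """
    f0, f1, dur = spec.f_start, spec.f_end, spec.duration
    if jitter_sd > 0:
        if rng is None:
            raise ValueError("jitter_sd > 0 requires an rng")
        g = 1.0 + rng.normal(0.0, jitter_sd, size=3)
        g = np.clip(g, 0.2, 5.0)
        f0, f1, dur = f0 * g[0], f1 * g[1], dur * g[2]
    nyq = sample_rate / 2.0
    if max(f0, f1) >= nyq:
        raise ValueError(
            f"sweep frequency {max(f0, f1):.0f} Hz at or above Nyquist ({nyq:.0f} Hz)"
        )
    n = max(int(round(dur * sample_rate)), 8)
    t = np.arange(n) / sample_rate
    if spec.sweep_shape == "linear":
        phase = 2 * np.pi * (f0 * t + 0.5 * (f1 - f0) / dur * t**2)
    elif spec.sweep_shape == "exponential":
        k = (f1 / f0) ** (1.0 / dur)
        phase = 2 * np.pi * f0 * (k**t - 1.0) / np.log(k) if f1 != f0 else 2 * np.pi * f0 * t
    else:
        raise ValueError(f"unknown sweep_shape {spec.sweep_shape!r}")
    return np.sin(phase) * _envelope(spec.amplitude_envelope, n)


def synth_trill(
    gt: TrillGroundTruth,
    sample_rate: float = 48000,
    rng: np.random.Generator | None = None,
    snr_db: float | None = 30.0,
    start_s: float = 0.0,
    duty: float = 0.75,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Render a trill and its per-syllable annotations.

    Syllables are downward sweeps from ``pitch`` spanning the (envelope-
    corrected) target bandwidth, spaced so that the realized syllable count
    over the realized onset->offset span equals ``gt.rate`` exactly in the
    jitter-free case.  Returns the waveform (background noise included when
    ``snr_db`` is not None) and annotation rows with times offset by
    ``start_s``.
    """
    if rng is None:
        rng = np.random.default_rng()
    n, T = gt.n_syllables, gt.rate
    d_syl = duty / T
    period = (n / T - d_syl) / (n - 1)
    if d_syl >= period:
        raise ValueError("infeasible trill: syllable duration >= period")
    span = gt.bandwidth * span_correction()
    f_hi = gt.pitch
    f_lo = max(f_hi - span, 50.0)
    if f_hi >= sample_rate / 2:
        raise ValueError("trill pitch at or above Nyquist")
    spec = SyllableSpec(f_start=f_hi, f_end=f_lo, duration=d_syl)

    total = int(round((n - 1) * period * sample_rate)) + int(round(d_syl * sample_rate)) + 8
    wave = np.zeros(total)
    rows = []
    for k in range(n):
        syl = synth_syllable(spec, sample_rate, jitter_sd=gt.jitter_sd, rng=rng)
        i0 = int(round(k * period * sample_rate))
        i1 = min(i0 + syl.size, total)
        wave[i0:i1] += syl[: i1 - i0]
        rows.append(
            {
                "syllable_idx": k,
                "begin_s": start_s + i0 / sample_rate,
                "end_s": start_s + i1 / sample_rate,
                "low_hz": min(spec.f_start, spec.f_end),
                "high_hz": max(spec.f_start, spec.f_end),
                "trill_type": gt.trill_type,
            }
        )
    if snr_db is not None:
        rms = np.sqrt(np.mean(wave[wave != 0] ** 2)) if np.any(wave != 0) else 1.0
        wave = wave + rng.normal(0.0, rms * 10 ** (-snr_db / 20.0), size=wave.size)
    return wave, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# trill cloud
# ---------------------------------------------------------------------------


def simulate_trill_cloud(
    n: int,
    slope: float = -168.50,
    intercept: float = 6019.0,
    rng: np.random.Generator | None = None,
    rate_range: tuple[float, float] = (3.5, 15.5),
    deviation_mean: float = 8.2,
    deviation_sd: float = 3.0,
    distribution: str = "exponential",
    min_bandwidth: float = 600.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Sample a (rate, bandwidth) cloud lying under a linear performance limit.

    Orthogonal deviations from the limit decay exponentially by default,
    giving the triangular cloud with density approaching the frontier that
    trill-performance data show and that upper-bound regression presumes; a
    ``"gaussian"`` mode instead places a constant-width band below the line
    (bin maxima then sit clear of the frontier and the fitted limit is
    noisier).  Every point satisfies ``B <= slope*T + intercept``.
    """
    if rng is None:
        rng = np.random.default_rng()
    T = rng.uniform(*rate_range, size=n)
    if distribution == "gaussian":
        D = rng.normal(deviation_mean, deviation_sd, size=n)
        D = np.clip(D, 0.05, None)
    elif distribution == "exponential":
        D = rng.exponential(deviation_mean, size=n) + 0.02
    else:
        raise ValueError(f"unknown deviation distribution {distribution!r}")
    B = slope * T + intercept - D * np.sqrt(1 + slope**2)
    B = np.clip(B, min_bandwidth, None)
    return T, B


# ---------------------------------------------------------------------------
# the study bundle
# ---------------------------------------------------------------------------


@dataclass
class StudyBundle:
    """All simulated inputs plus ground truth.

    ``trills`` holds per-trill latent truth; ``measures`` the tabular
    (measurement-noise-added) per-trill measures usable directly by the
    statistics stages; audio is rendered on demand with
    :meth:`render_male_year`.
    """

    config: PopulationConfig
    male_years: pd.DataFrame
    trills: pd.DataFrame
    measures: pd.DataFrame
    phenotype: pd.DataFrame
    behavior: pd.DataFrame
    genotypes: pd.DataFrame
    nests: pd.DataFrame
    ground_truth: dict

    def render_male_year(self, male_id: str, year: int):
        """Deterministically render (waveform, annotation table) for one
        male-year from its stored child seed."""
        row = self.male_years[
            (self.male_years.male_id == male_id) & (self.male_years.year == year)
        ]
        if row.empty:
            raise KeyError(f"no such male-year: {male_id}/{year}")
        rng = np.random.default_rng(int(row.audio_seed.iloc[0]))
        trills = self.trills[
            (self.trills.male_id == male_id) & (self.trills.year == year)
        ].sort_values("trill_id")
        sr = self.config.sample_rate
        song_gap, trill_gap = 0.25, 0.15
        t_cursor = 0.1
        waves, ann_rows = [np.zeros(int(t_cursor * sr))], []
        for song_id, grp in trills.groupby("song_id", sort=True):
            for _, tr in grp.iterrows():
                gt = TrillGroundTruth(
                    male_id=male_id,
                    year=year,
                    trill_type=int(tr.trill_type),
                    rate=float(tr.rate),
                    bandwidth=float(tr.bandwidth),
                    pitch=float(tr.pitch),
                    jitter_sd=float(tr.jitter_sd),
                    n_syllables=int(tr.n_syllables),
                    time_in_song=float(tr.time_in_song),
                )
                wave, ann = synth_trill(
                    gt, sr, rng=rng, snr_db=self.config.snr_db, start_s=t_cursor
                )
                ann.insert(0, "trill_id", tr.trill_id)
                ann.insert(0, "song_id", song_id)
                waves.append(wave)
                ann_rows.append(ann)
                t_cursor += wave.size / sr + trill_gap
                waves.append(np.zeros(int(trill_gap * sr)))
            t_cursor += song_gap - trill_gap
            waves[-1] = np.zeros(int(song_gap * sr))
        waveform = np.concatenate(waves) if waves else np.zeros(sr)
        annotations = pd.concat(ann_rows, ignore_index=True)
        annotations.insert(0, "file", f"{male_id}_{year}.wav")
        return waveform, annotations

    def write(self, out_dir, audio: bool = False) -> Path:
        """Write the bundle as plain-text CSV/TSV/JSON (and WAVs if asked)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.male_years.to_csv(out / "male_years.csv", index=False)
        self.trills.to_csv(out / "trills_truth.csv", index=False)
        self.measures.to_csv(out / "measures_true.csv", index=False)
        self.phenotype.to_csv(out / "phenotype.csv", index=False)
        self.behavior.to_csv(out / "behavior.csv", index=False)
        self.genotypes.to_csv(out / "genotypes.csv", index=False)
        self.nests.to_csv(out / "nests.csv", index=False)
        with open(out / "ground_truth.json", "w") as fh:
            json.dump(self.ground_truth, fh, indent=1, sort_keys=True, default=float)
        cfg = asdict(self.config)
        cfg["allele_freqs"] = [list(map(float, f)) for f in cfg["allele_freqs"]]
        with open(out / "config.json", "w") as fh:
            json.dump(cfg, fh, indent=1, default=str)
        if audio:
            adir = out / "audio"
            tdir = out / "annotations"
            adir.mkdir(exist_ok=True)
            tdir.mkdir(exist_ok=True)
            for _, my in self.male_years.iterrows():
                wave, ann = self.render_male_year(my.male_id, int(my.year))
                pcm = np.clip(wave, -1, 1)
                wavfile.write(
                    adir / f"{my.male_id}_{my.year}.wav",
                    self.config.sample_rate,
                    (pcm * 32767).astype(np.int16),
                )
                ann.to_csv(
                    tdir / f"{my.male_id}_{my.year}.txt", sep="\t", index=False
                )
        return out


def load_bundle(in_dir) -> StudyBundle:
    """Load a bundle previously written with :meth:`StudyBundle.write`."""
    p = Path(in_dir)
    with open(p / "config.json") as fh:
        cfg = json.load(fh)
    for key in ("years", "trills_per_male"):
        cfg[key] = tuple(cfg[key])
    config = PopulationConfig(**cfg)
    with open(p / "ground_truth.json") as fh:
        gt = json.load(fh)
    return StudyBundle(
        config=config,
        male_years=pd.read_csv(p / "male_years.csv"),
        trills=pd.read_csv(p / "trills_truth.csv"),
        measures=pd.read_csv(p / "measures_true.csv"),
        phenotype=pd.read_csv(p / "phenotype.csv"),
        behavior=pd.read_csv(p / "behavior.csv"),
        genotypes=pd.read_csv(p / "genotypes.csv"),
        nests=pd.read_csv(p / "nests.csv"),
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# population simulation
# ---------------------------------------------------------------------------


def _effect(cfg: PopulationConfig, trait: str, outcome: str) -> float:
    return float(cfg.effect_sizes.get(trait, {}).get(outcome, 0.0))


def _logit(p: float) -> float:
    return float(np.log(p / (1 - p)))


def _sample_true_genotype(cfg, rng) -> list[tuple[int, int]]:
    """True diploid genotype; allele id -1 is a null (non-amplifying) allele."""
    g = []
    for freqs, nf in zip(cfg.allele_freqs, cfg.null_allele_freq):
        alleles = []
        for _ in range(2):
            if rng.random() < nf:
                alleles.append(-1)
            else:
                # visible allele ids are fragment sizes: 100, 102, 104, ...
                alleles.append(100 + 2 * int(rng.choice(len(freqs), p=freqs)))
        g.append(tuple(alleles))
    return g


def _transmit(allele_pair, cfg, rng) -> int:
    a = allele_pair[int(rng.integers(2))]
    if a != -1 and rng.random() < cfg.mutation_rate:
        a += 2 if rng.random() < 0.5 else -2
    return a


def _observe(pair) -> tuple[int, int]:
    """Observed genotype: nulls hide behind the visible allele; two nulls
    (or a transmitted null with nothing visible) score as missing (0, 0)."""
    a, b = pair
    if a == -1 and b == -1:
        return (0, 0)
    if a == -1:
        return (b, b)
    if b == -1:
        return (a, a)
    return (min(a, b), max(a, b))


def _genotype_row(ind_id, role, year, nest_id, mother_id, father_id, true_g, n_loci):
    row = {
        "id": ind_id,
        "role": role,
        "year": year,
        "nest_id": nest_id,
        "mother_id": mother_id,
        "social_father_id": father_id,
    }
    for k in range(n_loci):
        a1, a2 = _observe(true_g[k])
        row[f"L{k + 1}_a1"] = a1
        row[f"L{k + 1}_a2"] = a2
    return row


def simulate_population(config: PopulationConfig) -> StudyBundle:
    """Simulate the full study: song, phenotype, behavior, nests, genotypes.

    All randomness flows from ``config.seed``; equal configs give identical
    bundles.  Ground truth (true sires, latent abilities, per-male-year
    success fields, limit coefficients, target repeatabilities) is stored in
    ``bundle.ground_truth``.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    n_types = cfg.n_types

    male_ids = [f"M{i + 1:03d}" for i in range(cfg.n_males)]
    # latent singing abilities (standard scale per trait)
    z_dev = rng.normal(0, np.sqrt(cfg.var_between["deviation"]), cfg.n_males)
    z_con = rng.normal(0, np.sqrt(cfg.var_between["consistency"]), cfg.n_males)
    sd_dev_b = np.sqrt(cfg.var_between["deviation"]) or 1.0
    sd_con_b = np.sqrt(cfg.var_between["consistency"]) or 1.0
    zs_dev = z_dev / sd_dev_b  # standardized male effects used in effect injection
    zs_con = z_con / sd_con_b

    # which males appear in which years (a subset recorded in both seasons)
    both = set(rng.choice(cfg.n_males, size=min(cfg.n_both_years, cfg.n_males), replace=False))
    years_of = {}
    for i in range(cfg.n_males):
        if i in both or len(cfg.years) == 1:
            years_of[i] = list(cfg.years)
        else:
            years_of[i] = [cfg.years[int(rng.integers(len(cfg.years)))]]

    # per-type acoustic baselines: rate, pitch, small type effects on traits
    type_rate = np.linspace(4.5, 13.5, n_types)
    type_pitch = rng.uniform(5200, 7200, n_types)
    type_dev_eff = rng.normal(0, 0.6, n_types)
    type_con_eff = rng.normal(0, 0.12, n_types)

    sqrt1a2 = np.sqrt(1 + cfg.a_true**2)
    my_rows, trill_rows = [], []
    audio_seed_rng = np.random.default_rng(rng.integers(2**31))
    for i, mid in enumerate(male_ids):
        for year in years_of[i]:
            n_trills = int(rng.integers(cfg.trills_per_male[0], cfg.trills_per_male[1] + 1))
            my_rows.append(
                {
                    "male_id": mid,
                    "year": year,
                    "n_trills": n_trills,
                    "audio_seed": int(audio_seed_rng.integers(2**31)),
                    "z_deviation": z_dev[i],
                    "z_consistency": z_con[i],
                }
            )
            # group trills into songs of 1-3 trills (mean ~2)
            song_sizes = rng.choice([1, 2, 3], size=n_trills, p=[0.25, 0.5, 0.25])
            song_id, placed, k = 0, 0, 0
            while placed < n_trills:
                size = int(song_sizes[song_id % n_trills])
                size = min(size, n_trills - placed)
                t_in_song = 0.0
                for j in range(size):
                    ttype = int(rng.integers(n_types))
                    T = float(np.clip(type_rate[ttype] + rng.normal(0, 1.2), 3.2, 15.8))
                    e_dev = rng.normal(0, np.sqrt(cfg.var_within["deviation"]))
                    if cfg.deviation_distribution == "gaussian":
                        D = cfg.deviation_mean + cfg.deviation_sd * (
                            (z_dev[i] + e_dev) + type_dev_eff[ttype]
                        )
                        D = float(np.clip(D, 0.05, None))
                    else:  # exponential marginal via Gaussian copula
                        from scipy.stats import norm

                        u = norm.cdf(
                            (z_dev[i] + e_dev + type_dev_eff[ttype])
                            / np.sqrt(
                                cfg.var_between["deviation"] + cfg.var_within["deviation"]
                            )
                        )
                        D = float(-cfg.deviation_mean * np.log1p(-np.clip(u, 0, 1 - 1e-12)))
                    B = cfg.a_true * T + cfg.b_true - D * sqrt1a2
                    B = float(np.clip(B, 600.0, None))
                    D = (cfg.a_true * T + cfg.b_true - B) / sqrt1a2
                    e_con = rng.normal(0, np.sqrt(cfg.var_within["consistency"]))
                    c_star = cfg.consistency_mean + cfg.consistency_sd * (
                        (z_con[i] + e_con) + type_con_eff[ttype]
                    )
                    c_star = float(np.clip(c_star, 0.05, 6.0))
                    C = 1.0 - np.exp(-c_star)
                    pitch = float(max(type_pitch[ttype] + rng.normal(0, 150), B + 500))
                    n_syl = int(rng.integers(4, 11))
                    duration = n_syl / T
                    trill_rows.append(
                        {
                            "male_id": mid,
                            "year": year,
                            "song_id": f"{mid}_{year}_S{song_id:03d}",
                            "trill_id": f"{mid}_{year}_T{k:04d}",
                            "trill_type": ttype + 1,
                            "rate": T,
                            "bandwidth": B,
                            "pitch": pitch,
                            "duration": duration,
                            "time_in_song": t_in_song,
                            "n_syllables": n_syl,
                            "deviation_true": D,
                            "consistency_true": C,
                            "c_star_true": c_star,
                            "jitter_sd": float(np.clip(0.12 * (1.0 - C), 0.0, 0.12)),
                        }
                    )
                    t_in_song += duration + 0.15
                    k += 1
                placed += size
                song_id += 1

    male_years = pd.DataFrame(my_rows)
    trills = pd.DataFrame(trill_rows)

    # tabular measures: add small measurement noise, keep under the limit
    m = trills[
        [
            "male_id",
            "year",
            "song_id",
            "trill_id",
            "trill_type",
            "rate",
            "bandwidth",
            "pitch",
            "duration",
            "time_in_song",
            "n_syllables",
        ]
    ].copy()
    m["bandwidth"] = m["bandwidth"] + rng.normal(
        0, cfg.measurement_noise_bandwidth, len(m)
    )
    m["bandwidth"] = np.minimum(
        m["bandwidth"], cfg.a_true * m["rate"] + cfg.b_true - 1e-6
    )
    m["consistency"] = np.clip(
        trills["consistency_true"]
        + rng.normal(0, cfg.measurement_noise_consistency, len(m)),
        0.0,
        0.999999,
    )

    # ---- phenotype ----------------------------------------------------
    tarsus0 = rng.normal(16.8, 0.45, cfg.n_males)
    ages = {}  # (male, year) -> SY/ASY
    first_band = {}
    for i, mid in enumerate(male_ids):
        y0 = min(years_of[i])
        if rng.random() < 0.25:
            first_band[mid] = (y0 - 1, "nestling")
        elif rng.random() < 0.7:
            first_band[mid] = (y0 - int(rng.integers(1, 3)), "adult")
        else:
            first_band[mid] = (y0, "adult")  # first seen this year -> age unknown
    ph_rows = []
    for i, mid in enumerate(male_ids):
        for year in years_of[i]:
            band_year, band_stage = first_band[mid]
            if band_stage == "nestling" and band_year == year - 1:
                age = "SY"
            elif band_year < year:
                age = "ASY"
            else:
                age = ""
            ages[(mid, year)] = age
            asy = 1.0 if age == "ASY" else 0.0
            n_cap = int(rng.integers(1, 3))
            for _ in range(n_cap):
                day = float(rng.uniform(120, 210))
                hour = float(rng.uniform(6, 19))
                tarsus = tarsus0[i] + rng.normal(0, 0.08)
                wing = 49.7 + 1.5 * asy + rng.normal(0, 0.7)
                tail = 43.0 + 0.5 * asy + rng.normal(0, 1.3)
                weight = (
                    10.5
                    + 0.6 * (tarsus - 16.8)
                    + 0.004 * (day - 165)
                    + 0.015 * (hour - 12)
                    + rng.normal(0, 0.35)
                )
                ph_rows.append(
                    {
                        "male_id": mid,
                        "year": year,
                        "capture_day": day,
                        "capture_hour": hour,
                        "tarsus": tarsus,
                        "wing": wing,
                        "tail": tail,
                        "weight": weight,
                        "hl_ratio": float(np.exp(rng.normal(-0.45, 0.5))),
                        "bactericidal": float(np.clip(rng.beta(6, 1.2), 0, 1)),
                        "first_band_year": first_band[mid][0],
                        "first_band_stage": first_band[mid][1],
                    }
                )
    phenotype = pd.DataFrame(ph_rows)

    # ---- playback behavior logs ---------------------------------------
    beh_rows = []
    trial_len, bout_len = 360.0, 60.0
    bout_starts = (30.0, 150.0, 270.0)
    song_rate_m = np.exp(rng.normal(np.log(6.0), 0.35, cfg.n_males))  # songs/min
    p_close_m = rng.beta(2.5, 3.0, cfg.n_males)
    flight_rate_m = np.exp(rng.normal(np.log(1.5), 0.5, cfg.n_males))  # per bout
    for i, mid in enumerate(male_ids):
        for year in years_of[i]:
            trial = f"{mid}_{year}_PB"
            n_songs = rng.poisson(song_rate_m[i] * trial_len / 60.0)
            for t in np.sort(rng.uniform(0, trial_len, n_songs)):
                beh_rows.append(
                    dict(trial_id=trial, male_id=mid, year=year, event_type="song",
                         t_start=float(t), t_end=float(t))
                )
            for b0 in bout_starts:
                beh_rows.append(
                    dict(trial_id=trial, male_id=mid, year=year, event_type="bout",
                         t_start=b0, t_end=b0 + bout_len)
                )
                frac = float(np.clip(p_close_m[i] + rng.normal(0, 0.1), 0, 1))
                if frac > 0:
                    beh_rows.append(
                        dict(trial_id=trial, male_id=mid, year=year,
                             event_type="position", t_start=b0,
                             t_end=b0 + frac * bout_len)
                    )
                for _ in range(rng.poisson(flight_rate_m[i])):
                    t = float(rng.uniform(b0, b0 + bout_len))
                    beh_rows.append(
                        dict(trial_id=trial, male_id=mid, year=year,
                             event_type="crossing", t_start=t, t_end=t)
                    )
    behavior = pd.DataFrame(beh_rows)

    # ---- nests, paternity, genotypes ----------------------------------
    b_poly = _logit(max(min(cfg.polygyny_rate, 1 - 1e-6), 1e-6))
    b_ep = _logit(max(min(cfg.ep_rate, 1 - 1e-6), 1e-6))
    true_g = {mid: _sample_true_genotype(cfg, rng) for mid in male_ids}
    geno_rows, nest_rows, off_truth = [], [], []
    females_seen = set()
    fem_counter = 0
    n_loci = cfg.n_loci
    true_success = {}

    for year in cfg.years:
        present = [male_ids[i] for i in range(cfg.n_males) if year in years_of[i]]
        idx_of = {m: male_ids.index(m) for m in present}
        for mid in present:
            true_success[(mid, year)] = dict(
                n_social=0, n_wp=0, n_ep_sired=0, polygynous=False
            )
        # polygyny draws
        poly = {}
        for mid in present:
            i = idx_of[mid]
            lp = (
                b_poly
                + _effect(cfg, "deviation", "polygyny") * -zs_dev[i]
                + _effect(cfg, "consistency", "polygyny") * zs_con[i]
            )
            poly[mid] = rng.random() < 1 / (1 + np.exp(-lp))
            true_success[(mid, year)]["polygynous"] = bool(poly[mid])
        # EP sire sampling weights (softmax over present males)
        w = np.exp(
            np.array(
                [
                    _effect(cfg, "deviation", "ep_success") * -zs_dev[idx_of[m]]
                    + _effect(cfg, "consistency", "ep_success") * zs_con[idx_of[m]]
                    for m in present
                ]
            )
        )
        for mid in present:
            i = idx_of[mid]
            n_nests = 2 if poly[mid] else 1
            primary_range = None
            for nest_no in range(n_nests):
                fem_counter += 1
                fid = f"F{fem_counter:03d}"
                females_seen.add(fid)
                fg = _sample_true_genotype(cfg, rng)
                nest_id = f"{mid}_{year}_N{nest_no + 1}"
                if nest_no == 0:
                    begin = float(rng.uniform(120, 160))
                    primary_range = (begin, begin + 35.0)
                else:
                    # simultaneous polygyny: overlap the primary's active window
                    begin = float(rng.uniform(primary_range[0] + 5, primary_range[1] - 10))
                end = begin + 35.0
                brood = int(np.clip(1 + rng.poisson(cfg.mean_brood - 1), 1, 8))
                nest_rows.append(
                    {
                        "nest_id": nest_id,
                        "year": year,
                        "male_id": mid,
                        "female_id": fid,
                        "begin_day": begin,
                        "end_day": end,
                        "n_banded": brood,
                        "is_secondary": int(nest_no == 1),
                        "exclude_desertion": 0,
                        "exclude_mate_switch": 0,
                        "exclude_brood_manip": 0,
                    }
                )
                geno_rows.append(
                    _genotype_row(fid, "adult_female", year, nest_id, "", "", fg, n_loci)
                )
                # offspring
                p_ep = 1 / (
                    1
                    + np.exp(
                        -(
                            b_ep
                            - _effect(cfg, "deviation", "wp") * -zs_dev[i]
                            - _effect(cfg, "consistency", "wp") * zs_con[i]
                        )
                    )
                )
                for c in range(brood):
                    oid = f"{nest_id}_O{c + 1}"
                    is_ep = (rng.random() < p_ep) and len(present) > 1
                    if is_ep:
                        others = [m for m in present if m != mid]
                        wo = np.array([w[present.index(m)] for m in others])
                        sire = str(rng.choice(others, p=wo / wo.sum()))
                    else:
                        sire = mid
                    og = []
                    for loc in range(n_loci):
                        og.append(
                            (
                                _transmit(fg[loc], cfg, rng),
                                _transmit(true_g[sire][loc], cfg, rng),
                            )
                        )
                    geno_rows.append(
                        _genotype_row(
                            oid, "offspring", year, nest_id, fid, mid, og, n_loci
                        )
                    )
                    off_truth.append(
                        {
                            "offspring_id": oid,
                            "nest_id": nest_id,
                            "year": year,
                            "mother_id": fid,
                            "social_father_id": mid,
                            "true_sire": sire,
                            "is_ep": bool(is_ep),
                        }
                    )
                    true_success[(mid, year)]["n_social"] += 1
                    if is_ep:
                        true_success[(sire, year)]["n_ep_sired"] += 1
                    else:
                        true_success[(mid, year)]["n_wp"] += 1
        for mid in present:
            geno_rows.append(
                _genotype_row(
                    mid, "adult_male", year, "", "", "", true_g[mid], n_loci
                )
            )

    genotypes = pd.DataFrame(geno_rows).drop_duplicates(subset=["id", "year"])
    nests = pd.DataFrame(nest_rows)

    succ_rows = []
    for (mid, year), s in true_success.items():
        wp_prop = s["n_wp"] / s["n_social"] if s["n_social"] else np.nan
        succ_rows.append(
            {
                "male_id": mid,
                "year": year,
                "wp_proportion": wp_prop,
                "ep_success": s["n_ep_sired"] > 0,
                "polygynous": s["polygynous"],
                "annual_rs": s["n_wp"] + s["n_ep_sired"],
                "n_social": s["n_social"],
                "n_ep_sired": s["n_ep_sired"],
            }
        )

    gt = {
        "limit_slope": cfg.a_true,
        "limit_intercept": cfg.b_true,
        "repeatability_deviation": cfg.var_between["deviation"]
        / (cfg.var_between["deviation"] + cfg.var_within["deviation"]),
        "repeatability_consistency": cfg.var_between["consistency"]
        / (cfg.var_between["consistency"] + cfg.var_within["consistency"]),
        "effect_sizes": cfg.effect_sizes,
        "ep_rate": cfg.ep_rate,
        "n_ep_offspring": int(sum(o["is_ep"] for o in off_truth)),
        "n_offspring": len(off_truth),
        "offspring": off_truth,
        "male_year_success": succ_rows,
        "male_latent": {
            mid: {"z_deviation": float(z_dev[i]), "z_consistency": float(z_con[i])}
            for i, mid in enumerate(male_ids)
        },
    }

    return StudyBundle(
        config=cfg,
        male_years=male_years,
        trills=trills,
        measures=m,
        phenotype=phenotype,
        behavior=behavior,
        genotypes=genotypes,
        nests=nests,
        ground_truth=gt,
    )
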