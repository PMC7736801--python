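"""Stochastic simulator of a droplet-ordered single-molecule sequencing run.

The physical picture being emulated: single dNTPs are cleaved from a trapped
DNA strand in template order (pyrophosphorolysis) and captured by a stream of
microdroplets passing over the strand at a fixed rate.  Because release is not
synchronised with droplet passage, a droplet may capture zero, one or several
consecutive bases; within-droplet order is lost.  Each captured or contaminant
dNTP lights up one fluorescence channel of the droplet, and the droplet stream
is read out in acquisition order, so droplet order carries the sequence.

The generative model, per droplet:

* captured count ``k ~ Poisson(capture_rate)``, truncated so the cumulative
  capture never runs past the end of the reference; the captured bases are the
  next ``k`` consecutive reference bases, stored as an unordered multiset;
* independently per colour, a contaminant dNTP of that colour appears with
  probability ``contamination_rate`` (the stochastic-false-positive channel);
* each dNTP present reports its mapped channel, except with probability
  ``misidentify_rate`` it reports a uniformly chosen wrong channel;
* per channel, the measured intensity is drawn from the "occupied" mixture
  component if the channel was reported, else from the "unoccupied" one.
  Droplets holding several same-colour dNTPs draw from the same occupied
  component: one-or-more is modelled as a single population.

Intensities are log-normal on the linear scale (Gaussian on log10 intensity)
by default; a heavier-tailed location-scale Student-t variant on log10
intensity is available via the ``family`` tag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.stats import norm, truncnorm

__all__ = [
    "BASES",
    "DEFAULT_CHANNEL_MAP",
    "ChannelComponents",
    "IntensityModel",
    "SimConfig",
    "DropletTruth",
    "DropletRecord",
    "calibrate_intensity_model",
    "default_intensity_model",
    "solve_capture_rate",
    "poisson_occupancy",
    "poisson_multi_fraction",
    "make_reference",
    "simulate_release",
    "simulate_blanks",
    "render_intensities",
    "simulate_methyl_plate",
]

BASES = ("A", "C", "G", "T")

#: Default base -> channel assignment.  532 nm carries dATP and 655 nm dGTP
#: (the two colours shown in the example droplet-array images); the 594 and
#: 701 nm assignments are conventional and configurable.
DEFAULT_CHANNEL_MAP: dict[str, str] = {
    "A": "ch532",
    "C": "ch594",
    "G": "ch655",
    "T": "ch701",
}

METHYL_CHANNELS = ("ch1", "ch2")

#: Droplets larger than this are removed upstream of the device.
DIAMETER_CAP_UM = 15.0


# ---------------------------------------------------------------------------
# intensity model


@dataclass(frozen=True)
class ChannelComponents:
    """Two-component intensity model for one channel, on log10 intensity."""

    unoccupied_loc: float
    unoccupied_scale: float
    occupied_loc: float
    occupied_scale: float

    def __post_init__(self) -> None:
        if self.unoccupied_scale <= 0 or self.occupied_scale <= 0:
            raise ValueError("component scales must be positive")
        if self.occupied_loc <= self.unoccupied_loc:
            raise ValueError("occupied location must exceed unoccupied location")


@dataclass(frozen=True)
class IntensityModel:
    """Per-channel two-component heavy-tailed intensity model.

    Parameters
    ----------
    components
        Mapping channel name -> :class:`ChannelComponents` (log10-intensity
        locations and scales).
    occupied_weight
        Prior fraction of occupied droplets used for calibration of the
        crossing point (default 0.30).
    family
        ``"lognormal"`` (Gaussian on log10 intensity, the default) or
        ``"log-t"`` (location-scale Student-t on log10 intensity with ``df``
        degrees of freedom).
    """

    components: Mapping[str, ChannelComponents]
    occupied_weight: float = 0.30
    family: str = "lognormal"
    df: float = 5.0

    def __post_init__(self) -> None:
        if not 0.0 < self.occupied_weight < 1.0:
            raise ValueError("occupied_weight must lie in (0, 1)")
        if self.family not in ("lognormal", "log-t"):
            raise ValueError(f"unknown intensity family {self.family!r}")
        if self.family == "log-t" and self.df <= 2:
            raise ValueError("log-t family requires df > 2")
        object.__setattr__(self, "components", dict(self.components))

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(self.components)


def calibrate_intensity_model(
    channels: Sequence[str] = tuple(DEFAULT_CHANNEL_MAP.values()),
    *,
    fp_overlap: float = 8e-4,
    fn_overlap: float = 0.016,
    unoccupied_loc: float = 2.0,
    unoccupied_scale: float = 0.10,
    occupied_weight: float = 0.30,
) -> IntensityModel:
    """Solve for occupied-component parameters hitting given overlap rates.

    The crossing point ``c`` of the weighted component densities acts as the
    effective call threshold; the overlap false-positive rate is the mass of
    the unoccupied component above ``c`` and the overlap false-negative rate
    the mass of the occupied component below ``c``.  Given the unoccupied
    component and the mixture weight, both targets pin down the occupied
    component in closed form:

    * ``c = mu0 + s0 * z(1 - fp)`` places the unoccupied upper tail;
    * the density-equality condition at ``c`` fixes the occupied scale;
    * ``(c - mu1)/s1 = z(fn)`` then fixes the occupied location.

    The same components are used for every channel.
    """
    if not 0 < fp_overlap < 0.5 or not 0 < fn_overlap < 0.5:
        raise ValueError("overlap targets must lie in (0, 0.5)")
    mu0, s0, w = unoccupied_loc, unoccupied_scale, occupied_weight
    crossing = mu0 + s0 * norm.ppf(1.0 - fp_overlap)
    z_fn = norm.ppf(fn_overlap)
    unocc_density = (1.0 - w) * norm.pdf((crossing - mu0) / s0) / s0
    s1 = w * norm.pdf(z_fn) / unocc_density
    mu1 = crossing - z_fn * s1
    comp = ChannelComponents(mu0, s0, mu1, s1)
    return IntensityModel(
        components={ch: comp for ch in channels}, occupied_weight=w
    )


def default_intensity_model(
    channels: Sequence[str] = tuple(DEFAULT_CHANNEL_MAP.values()),
) -> IntensityModel:
    """Paper-calibrated default: overlap FP 0.08 %, FN 1.6 % per colour."""
    return calibrate_intensity_model(channels)


# ---------------------------------------------------------------------------
# run configuration and record types


@dataclass(frozen=True)
class SimConfig:
    """All generative parameters of a simulated droplet sequencing run.

    ``capture_rate`` is the Poisson mean number of dNTPs released into one
    droplet.  The default 0.455 is the calibration at which 21 % of occupied
    droplets hold more than one base (see :func:`solve_capture_rate`).
    ``sampling_rate_hz`` records the droplet passage rate (0.5 Hz); it scales
    acquisition timestamps only and does not enter the statistics.
    """

    n_droplets: int
    seed: int
    capture_rate: float = 0.455
    sampling_rate_hz: float = 0.5
    contamination_rate: float = 0.031
    misidentify_rate: float = 0.001
    channel_map: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_CHANNEL_MAP)
    )
    intensity_model: IntensityModel | None = None

    def __post_init__(self) -> None:
        if self.n_droplets < 1:
            raise ValueError("n_droplets must be >= 1")
        if self.capture_rate <= 0:
            raise ValueError("capture_rate must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        for name in ("contamination_rate", "misidentify_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        cmap = dict(self.channel_map)
        if set(cmap) < set(BASES):
            raise ValueError("channel_map must cover A, C, G and T")
        if len(set(cmap.values())) != len(cmap):
            raise ValueError("channel_map must be a bijection (unique channels)")
        object.__setattr__(self, "channel_map", cmap)
        if self.intensity_model is None:
            model = default_intensity_model(tuple(cmap[b] for b in sorted(cmap)))
            object.__setattr__(self, "intensity_model", model)
        missing = set(cmap.values()) - set(self.intensity_model.channels)
        if missing:
            raise ValueError(f"intensity_model lacks channels {sorted(missing)}")

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted(set(self.channel_map.values())))

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class DropletTruth:
    """Ground truth for one droplet: what it captured and what it reports."""

    index: int
    captured: tuple[str, ...]  # sorted multiset of reference bases
    contaminants: tuple[str, ...]  # sorted multiset of contaminant bases
    reported_channels: Mapping[str, bool]

    def __post_init__(self) -> None:
        object.__setattr__(self, "captured", tuple(sorted(self.captured)))
        object.__setattr__(self, "contaminants", tuple(sorted(self.contaminants)))
        object.__setattr__(self, "reported_channels", dict(self.reported_channels))


@dataclass(frozen=True)
class DropletRecord:
    """One droplet's measured data: acquisition index, size, intensities."""

    index: int
    diameter_um: float
    intensity: Mapping[str, float]

    def __post_init__(self) -> None:
        vals = list(self.intensity.values())
        if not all(math.isfinite(v) and v > 0 for v in vals):
            raise ValueError(f"droplet {self.index}: intensities must be finite and positive")
        object.__setattr__(self, "intensity", dict(self.intensity))

    @property
    def channels(self) -> tuple[str, ...]:
        return tuple(sorted(self.intensity))


# ---------------------------------------------------------------------------
# closed-form occupancy statistics


def poisson_occupancy(rate: float) -> float:
    """P(k >= 1) for k ~ Poisson(rate)."""
    return -math.expm1(-rate)


def poisson_multi_fraction(rate: float) -> float:
    """P(k >= 2 | k >= 1) for k ~ Poisson(rate)."""
    p_ge1 = poisson_occupancy(rate)
    p_ge2 = p_ge1 - rate * math.exp(-rate)
    return p_ge2 / p_ge1


def solve_capture_rate(multi_fraction: float = 0.21) -> float:
    """Capture rate at which the given fraction of occupied droplets is multi-base.

    Root of ``(1 - e^-lam (1 + lam)) / (1 - e^-lam) = multi_fraction`` by
    bisection; at the 21 % operating point the root is ~0.454.
    """
    if not 0 < multi_fraction < 1:
        raise ValueError("multi_fraction must lie in (0, 1)")
    return brentq(
        lambda lam: poisson_multi_fraction(lam) - multi_fraction, 1e-9, 50.0, xtol=1e-12
    )


# ---------------------------------------------------------------------------
# reference construction


def make_reference(
    length: int,
    gc_target: float,
    homopolymer_len: int = 0,
    seed: int = 0,
) -> tuple[str, int | None]:
    """Random reference sequence with controlled GC content.

    Each position is G/C with probability ``gc_target`` (uniform within the
    strong or weak pair), so the realised GC fraction sits within binomial
    sampling error of the target.  If ``homopolymer_len`` > 0, a single run of
    one base of that length is embedded at a random position, emulating
    homopolymer stretches that trouble other single-molecule chemistries; the
    run base is A for AT-rich/balanced targets and G for GC-rich ones.

    Returns
    -------
    (sequence, homopolymer_start)
        ``homopolymer_start`` is the 0-based start of the embedded run, or
        ``None`` when no run was requested.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    if not 0.0 <= gc_target <= 1.0:
        raise ValueError("gc_target must lie in [0, 1]")
    if homopolymer_len < 0 or homopolymer_len > length:
        raise ValueError("homopolymer_len must lie in [0, length]")
    rng = np.random.default_rng(seed)
    strong = rng.random(length) < gc_target
    pick = rng.integers(0, 2, size=length)
    bases = np.where(strong, np.where(pick == 0, "G", "C"), np.where(pick == 0, "A", "T"))
    start: int | None = None
    if homopolymer_len > 0:
        start = int(rng.integers(0, length - homopolymer_len + 1))
        run_base = "G" if gc_target > 0.5 else "A"
        bases[start : start + homopolymer_len] = run_base
    return "".join(bases), start


# ---------------------------------------------------------------------------
# droplet-level simulation


def _report_channels(
    present: list[str],
    cfg: SimConfig,
    rng: np.random.Generator,
    channels: tuple[str, ...],
) -> dict[str, bool]:
    """Channel flags for the dNTPs present in one droplet.

    Each dNTP reports its mapped channel, except with probability
    ``misidentify_rate`` it reports one of the other channels uniformly.
    """
    flags = {ch: False for ch in channels}
    for base in present:
        ch = cfg.channel_map[base]
        if cfg.misidentify_rate > 0 and rng.random() < cfg.misidentify_rate:
            others = [c for c in channels if c != ch]
            ch = others[rng.integers(0, len(others))]
        flags[ch] = True
    return flags


def _contaminant_bases(
    cfg: SimConfig, rng: np.random.Generator, n: int
) -> list[list[str]]:
    """Per-droplet contaminant multisets: one Bernoulli trial per colour."""
    # colour c carries the base mapped to it; trials independent per droplet
    # and per colour.
    bases_by_channel = sorted(cfg.channel_map, key=cfg.channel_map.get)
    hits = rng.random((n, len(bases_by_channel))) < cfg.contamination_rate
    out: list[list[str]] = []
    for row in hits:
        out.append([b for b, h in zip(bases_by_channel, row) if h])
    return out


def simulate_release(reference: str, cfg: SimConfig) -> list[DropletTruth]:
    """Release-and-capture simulation against a reference sequence.

    Captured counts are Poisson(``capture_rate``), truncated so the cumulative
    number of captured bases never exceeds the reference length; droplet ``i``
    captures the next ``k_i`` consecutive reference bases (stored unordered).
    Contamination and channel misidentification are applied on top.  The
    concatenation of captured multisets in acquisition order always spells a
    prefix of the reference.
    """
    if not reference:
        raise ValueError("reference must be non-empty")
    bad = set(reference) - set(BASES)
    if bad:
        raise ValueError(f"reference contains non-ACGT symbols: {sorted(bad)}")
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_droplets
    counts = rng.poisson(cfg.capture_rate, n)
    ends = np.minimum(np.cumsum(counts), len(reference))
    starts = np.concatenate(([0], ends[:-1]))
    contaminants = _contaminant_bases(cfg, rng, n)
    channels = cfg.channels
    truths = []
    for i in range(n):
        captured = list(reference[starts[i] : ends[i]])
        present = captured + contaminants[i]
        truths.append(
            DropletTruth(
                index=i,
                captured=tuple(captured),
                contaminants=tuple(contaminants[i]),
                reported_channels=_report_channels(present, cfg, rng, channels),
            )
        )
    return truths


def simulate_blanks(cfg: SimConfig) -> list[DropletTruth]:
    """Droplets never passed over DNA: contamination and misreporting only.

    These arrays estimate the stochastic false-positive rate — per colour, the
    fraction of reported channels approaches ``contamination_rate``.
    """
    rng = np.random.default_rng(cfg.seed)
    contaminants = _contaminant_bases(cfg, rng, cfg.n_droplets)
    channels = cfg.channels
    return [
        DropletTruth(
            index=i,
            captured=(),
            contaminants=tuple(cont),
            reported_channels=_report_channels(list(cont), cfg, rng, channels),
        )
        for i, cont in enumerate(contaminants)
    ]


def _draw_log10(
    rng: np.random.Generator, model: IntensityModel, loc: np.ndarray, scale: np.ndarray
) -> np.ndarray:
    if model.family == "lognormal":
        z = rng.standard_normal(loc.shape)
    else:  # log-t: location-scale Student-t on log10 intensity
        z = rng.standard_t(model.df, loc.shape)
    return loc + scale * z


def _draw_diameters(rng: np.random.Generator, n: int) -> np.ndarray:
    # unimodal size distribution, capped at 15 um (larger droplets removed
    # before loading); cosmetic realism only.
    lo, hi, mu, sd = 4.0, DIAMETER_CAP_UM, 10.0, 1.5
    return truncnorm.rvs((lo - mu) / sd, (hi - mu) / sd, loc=mu, scale=sd, size=n, random_state=rng)


def render_intensities(
    truths: Sequence[DropletTruth],
    model: IntensityModel,
    seed: int,
) -> list[DropletRecord]:
    """Draw per-channel fluorescence intensities for simulated droplets.

    Channels flagged in ``reported_channels`` draw from that channel's
    occupied component, all others from the unoccupied component; a channel
    flagged by several dNTPs still draws once from the single occupied
    population.
    """
    rng = np.random.default_rng(seed)
    channels = model.channels
    n = len(truths)
    intensity = np.empty((n, len(channels)))
    for j, ch in enumerate(channels):
        comp = model.components[ch]
        flags = np.array([t.reported_channels.get(ch, False) for t in truths])
        loc = np.where(flags, comp.occupied_loc, comp.unoccupied_loc)
        scale = np.where(flags, comp.occupied_scale, comp.unoccupied_scale)
        intensity[:, j] = 10.0 ** _draw_log10(rng, model, loc, scale)
    diameters = _draw_diameters(rng, n)
    return [
        DropletRecord(
            index=t.index,
            diameter_um=float(diameters[i]),
            intensity={ch: float(intensity[i, j]) for j, ch in enumerate(channels)},
        )
        for i, t in enumerate(truths)
    ]


# ---------------------------------------------------------------------------
# methylation plate


METHYL_LABELS = ("empty", "dCTP", "5mdCTP")

#: Channel-1 fluoresces whenever a cytosine (methylated or not) is captured;
#: channel-2 is produced by a modification-sensitive restriction step and is
#: blocked by 5-methylcytosine, so it lights up for dCTP only.
_METHYL_OCCUPANCY = {
    "empty": (False, False),
    "dCTP": (True, True),
    "5mdCTP": (True, False),
}


def simulate_methyl_plate(
    n: int,
    fractions: tuple[float, float, float],
    model: IntensityModel | None = None,
    seed: int = 0,
) -> tuple[list[DropletRecord], list[str]]:
    """Two-channel dCTP / 5-methyl-dCTP plate.

    ``fractions`` are the (empty, dCTP, 5mdCTP) population fractions; droplet
    labels are drawn i.i.d. from them.  Returns the rendered records (channels
    ``ch1``, ``ch2``) together with the true label per droplet for recovery
    testing.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    frac = np.asarray(fractions, dtype=float)
    if frac.shape != (3,) or (frac < 0).any():
        raise ValueError("fractions must be three non-negative numbers")
    if not math.isclose(frac.sum(), 1.0, rel_tol=0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    if model is None:
        model = default_intensity_model(METHYL_CHANNELS)
    if set(METHYL_CHANNELS) - set(model.channels):
        raise ValueError("model must define channels 'ch1' and 'ch2'")
    rng = np.random.default_rng(seed)
    labels = [METHYL_LABELS[i] for i in rng.choice(3, size=n, p=frac)]
    truths = [
        DropletTruth(
            index=i,
            captured=(),
            contaminants=(),
            reported_channels=dict(zip(METHYL_CHANNELS, _METHYL_OCCUPANCY[lab])),
        )
        for i, lab in enumerate(labels)
    ]
    records = render_intensities(truths, model, seed=int(rng.integers(0, 2**31)))
    return records, labels
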