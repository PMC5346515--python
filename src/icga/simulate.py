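"""Synthetic resting-state fixtures with known ground truth.

The generator emulates what the graph-building method assumes about its
inputs and nothing more: component time-courses are band-limited
(0.01–0.1 Hz) Gaussian processes, mutually decorrelated over the sample;
regional BOLD courses are a signed linear mixture of the components plus
white noise at a controlled SNR; and an optional "painted" volume turns
the regional courses into a voxel grid with a box parcellation and
per-component spatial maps.  Courses are not convolved with a hemodynamic
response and carry no physiological or motion structure — the method
consumes only second-order statistics, so these simplifications do not
touch what the fixtures are for.

The default configuration is a 15-subject cohort, 3 components × 60
regions in signed blocks of 20 (component i loads +1 on block i and −1 on
block i+1 mod 3), 150 time points at TR = 2 s, SNR = 10.  Ground-truth
edge masks per component are returned for both flavors: the union of the
two same-sign block cliques (correlation) and the complete bipartite graph
between the opposite-sign blocks (anti-correlation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .types import ICDecomposition, ParcellationVolume, RegionTimeSeries


@dataclass
class SyntheticConfig:
    n_regions: int = 60
    n_components: int = 3
    n_timepoints: int = 150
    tr_seconds: float = 2.0
    band_hz: tuple = (0.01, 0.1)
    mixing: np.ndarray | None = None  # components × regions; None = signed blocks
    snr: float = 10.0
    volume_shape: tuple | None = None
    voxel_noise_sd: float = 0.05
    n_subjects: int = 15
    seed: int = 0

    def __post_init__(self):
        if self.n_timepoints <= self.n_components + 1:
            raise ValueError("n_timepoints must exceed n_components + 1")
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.mixing is not None:
            self.mixing = np.asarray(self.mixing, dtype=float)
            if self.mixing.shape != (self.n_components, self.n_regions):
                raise ValueError("mixing must be components × regions")

    def resolved_mixing(self) -> np.ndarray:
        if self.mixing is not None:
            return self.mixing
        return signed_block_mixing(self.n_components, self.n_regions)

    def subject_seed(self, subject_index: int) -> np.random.SeedSequence:
        return np.random.SeedSequence([int(self.seed), int(subject_index)])


def signed_block_mixing(
    n_components: int, n_regions: int, amplitude: float = 1.0
) -> np.ndarray:
    """Signed block mixing: +amplitude on block i, −amplitude on block i+1.

    Regions are split into ``n_components`` contiguous blocks; leftover
    regions (when n_regions is not divisible) stay unloaded, emulating
    parcels outside every network.
    """
    if n_components < 1 or n_regions < n_components:
        raise ValueError("need at least one region per component")
    block = n_regions // n_components
    m = np.zeros((n_components, n_regions))
    for i in range(n_components):
        m[i, i * block : (i + 1) * block] = amplitude
        j = (i + 1) % n_components
        m[i, j * block : (j + 1) * block] = -amplitude
    return m


def ground_truth_edges(mixing: np.ndarray, component: int, flavor: str) -> np.ndarray:
    """Boolean R×R mask of edges implied by the mixing signs for one component.

    Correlation edges join region pairs whose loadings on the component
    share a sign; anti-correlation edges join pairs of opposite sign.
    Unloaded regions (zero mixing) touch no edge.
    """
    sign = np.sign(mixing[component])
    prod = np.outer(sign, sign)
    if flavor == "correlation":
        mask = prod > 0
    elif flavor == "anticorrelation":
        mask = prod < 0
    else:
        raise ValueError(f"unknown flavor {flavor!r}")
    np.fill_diagonal(mask, False)
    return mask


def _band_indices(n_timepoints: int, tr: float, band_hz) -> np.ndarray:
    freqs = np.fft.rfftfreq(n_timepoints, d=tr)
    low, high = band_hz
    nyquist = 0.5 / tr
    if low >= nyquist:
        raise ValueError(
            f"band lower edge {low} Hz is at or above Nyquist {nyquist} Hz"
        )
    keep = (freqs >= low) & (freqs <= high) & (freqs > 0)
    if not keep.any():
        raise ValueError("no FFT bins fall inside the requested band")
    return keep


def make_component_timecourses(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> ICDecomposition:
    """Band-limited, unit-variance, mutually decorrelated component courses.

    White Gaussian noise is Fourier-filtered to the configured band, the
    courses are orthogonalised over the sample (QR; linear combinations of
    band-limited signals stay band-limited), and each is scaled to unit
    sample variance.  Zeroing the DC bin makes every course exactly
    mean-zero, so orthogonality equals zero sample correlation.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p, n = config.n_timepoints, config.n_components
    keep = _band_indices(p, config.tr_seconds, config.band_hz)
    if keep.sum() < n:
        raise ValueError(
            f"band carries {int(keep.sum())} bins, fewer than "
            f"{n} components to decorrelate"
        )
    white = rng.standard_normal((n, p))
    spectrum = np.fft.rfft(white, axis=1)
    spectrum[:, ~keep] = 0.0
    courses = np.fft.irfft(spectrum, n=p, axis=1)
    q, _ = np.linalg.qr(courses.T)  # P × N, orthonormal mean-zero columns
    courses = q.T
    courses /= courses.std(axis=1, ddof=0)[:, None]
    return ICDecomposition(
        timecourses=courses,
        tr_seconds=config.tr_seconds,
        component_ids=list(range(1, n + 1)),
    )


def make_region_timecourses(
    config: SyntheticConfig,
    decomposition: ICDecomposition,
    rng: np.random.Generator | None = None,
) -> tuple[RegionTimeSeries, np.ndarray]:
    """Regional courses Y = mixingᵀ·X + noise; returns (series, true mixing).

    Per-region white-noise variance is set so var(signal)/var(noise) equals
    the configured SNR on loaded regions; unloaded (zero-mixing) regions
    receive noise at the loaded regions' mean noise level, so they carry
    signal-free fluctuations rather than constant rows.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    mixing = config.resolved_mixing()
    if mixing.shape[0] != decomposition.n_components:
        raise ValueError("mixing does not match the decomposition")
    signal = mixing.T @ decomposition.timecourses  # R × P
    sig_var = signal.var(axis=1, ddof=0)
    loaded = sig_var > 0
    noise_var = np.empty_like(sig_var)
    noise_var[loaded] = sig_var[loaded] / config.snr
    baseline = noise_var[loaded].mean() if loaded.any() else 1.0
    noise_var[~loaded] = baseline
    noise = rng.standard_normal(signal.shape) * np.sqrt(noise_var)[:, None]
    series = RegionTimeSeries(
        values=signal + noise,
        region_ids=np.arange(1, config.n_regions + 1),
        tr_seconds=config.tr_seconds,
    )
    return series, mixing


def box_parcellation(volume_shape, n_regions: int) -> ParcellationVolume:
    """Partition the voxel grid into ``n_regions`` contiguous labeled chunks."""
    n_voxels = int(np.prod(volume_shape))
    if n_regions > n_voxels:
        raise ValueError("more regions than voxels")
    labels = np.repeat(
        np.arange(1, n_regions + 1),
        np.diff(np.linspace(0, n_voxels, n_regions + 1).astype(int)),
    ).reshape(volume_shape)
    return ParcellationVolume(labels=labels)


def paint_volume(
    config: SyntheticConfig,
    region_series: RegionTimeSeries,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, ParcellationVolume, np.ndarray]:
    """Expand regional courses onto a voxel grid with a box parcellation.

    Returns ``(bold_4d, parcellation, spatial_maps)``: each voxel carries
    its region's course plus small independent voxel noise, and the
    per-component spatial maps assign each voxel its region's mixing
    loading (zero outside the component's blocks).
    """
    if config.volume_shape is None:
        raise ValueError("volume_shape must be set to paint a volume")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    parc = box_parcellation(config.volume_shape, config.n_regions)
    lab = parc.labels.reshape(-1)
    courses = region_series.values  # R × P, rows align with labels 1..R
    voxel_courses = courses[lab - 1]  # V × P
    voxel_courses = voxel_courses + rng.standard_normal(
        voxel_courses.shape
    ) * config.voxel_noise_sd
    bold = voxel_courses.reshape(*config.volume_shape, courses.shape[1])
    mixing = config.resolved_mixing()
    maps = mixing[:, lab - 1].T.reshape(*config.volume_shape, mixing.shape[0])
    return bold, parc, maps


def simulate_subject(config: SyntheticConfig, subject_index: int = 0) -> dict:
    """All inputs for one synthetic subject, deterministically seeded.

    Returns a dict with ``decomposition``, ``series``, ``mixing`` and —
    when ``volume_shape`` is set — ``bold``, ``parcellation`` and a
    decomposition carrying spatial maps.
    """
    ss = config.subject_seed(subject_index)
    rngs = [np.random.default_rng(s) for s in ss.spawn(3)]
    decomposition = make_component_timecourses(config, rngs[0])
    series, mixing = make_region_timecourses(config, decomposition, rngs[1])
    out = {"decomposition": decomposition, "series": series, "mixing": mixing}
    if config.volume_shape is not None:
        bold, parc, maps = paint_volume(config, series, rngs[2])
        out["bold"] = bold
        out["parcellation"] = parc
        out["decomposition"] = ICDecomposition(
            timecourses=decomposition.timecourses,
            tr_seconds=config.tr_seconds,
            component_ids=decomposition.component_ids,
            spatial_maps=maps,
        )
    return out


def simulate_cohort(config: SyntheticConfig) -> list[dict]:
    """One :func:`simulate_subject` result per subject."""
    return [simulate_subject(config, i) for i in range(config.n_subjects)]
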