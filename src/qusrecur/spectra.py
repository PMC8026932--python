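"""Sliding-window spectral analysis and the seven QUS parameters.

The ROI is tiled with ~2 mm x 2 mm windows at 92 % overlap.  Per window, the
power spectrum (Hann taper per scan line, line-averaged periodogram,
zero-padded to >= 4x the window length) is divided by a reference-phantom
spectrum taken over the same depth span, cancelling the system response.

Estimators on the normalized band (3-8 MHz) spectrum:

* MBF / SS / SI  -- Lizzi-Feleppa straight-line fit in dB vs MHz; the
  mid-band fit is the line value at the center frequency, the intercept its
  extrapolation to 0 MHz, so MBF = SS * fc + SI holds identically.
* ASD / AAC      -- Gaussian (Insana-Hall) form-factor inversion: the log
  normalized power is regressed on k^2; the slope gives the effective
  scatterer radius via exp(-0.827 k^2 a^2), the intercept the acoustic
  concentration relative to the phantom's (self-calibrated).
* SAS            -- most prominent peak of the normalized spectral
  autocorrelation; a quasi-periodic scatterer spacing d ripples the power
  spectrum with period c/(2 d).  Spacing detection needs finer spectral
  resolution than the 2 mm window offers for spacings beyond ~1.3 mm, so SAS
  uses a dedicated longer axial gate centred on each window.
* ACE            -- reference-phantom spectral-difference method: the
  normalized log-spectrum decays linearly with depth at each frequency; the
  frequency slope of that decay rate gives the attenuation coefficient
  (per slice, halved for two-way propagation).

After ACE is known, every window spectrum is compensated by
+2 * ACE * f * z dB before the other estimators run; without this the
depth-dependent spectral tilt dominates the form-factor slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import GAUSS_FF_CONST, AcquisitionSpec

__all__ = [
    "WindowGrid",
    "SliceFeatures",
    "build_window_grid",
    "normalized_spectrum",
    "fit_mbf_ss_si",
    "estimate_asd_aac",
    "estimate_sas",
    "estimate_ace",
    "spectral_autocorrelation",
    "extract_slice",
    "ASD_RANGE_UM",
    "SAS_RANGE_MM",
]

WINDOW_MM = 2.0        # nominal window side, mm
OVERLAP = 0.92         # sliding-window overlap fraction
PAD_FACTOR = 4         # FFT length >= PAD_FACTOR * window samples
ASD_RANGE_UM = (1.0, 200.0)
SAS_RANGE_MM = (0.2, 2.5)
SAS_GATE_MM = 5.0      # dedicated axial gate length for spacing estimation
SAS_PROMINENCE = 0.1   # minimum normalized autocorrelation peak height
SAS_SMOOTH_HALF = 16   # lattice half-width (~2.5 mm) of autocorr averaging
AAC_REFERENCE_DB = 95.0  # phantom's nominal concentration on the dB scale

_LN10_over_10 = np.log(10.0) / 10.0
_10_over_LN10 = 10.0 / np.log(10.0)


@dataclass
class WindowGrid:
    """Window geometry for one slice: sizes, steps and retained positions."""

    window_axial: int
    window_lateral: int
    step_axial: int
    step_lateral: int
    cand_rows: np.ndarray       # candidate axial origins
    cand_cols: np.ndarray       # candidate lateral origins
    positions: np.ndarray       # (n, 2) retained (row, col) origins
    lattice_index: np.ndarray   # (n, 2) index of each window in the map lattice

    @property
    def n_windows(self) -> int:
        return len(self.positions)

    def centers(self) -> np.ndarray:
        """(n, 2) array of window-center pixel coordinates."""
        return self.positions + np.array(
            [self.window_axial // 2, self.window_lateral // 2])

    def map_shape(self) -> tuple[int, int]:
        return len(self.cand_rows), len(self.cand_cols)


def build_window_grid(slice_shape: tuple[int, int], mask: np.ndarray,
                      acq: AcquisitionSpec,
                      window_mm: float = WINDOW_MM) -> WindowGrid:
    """Tile a slice with overlapping analysis windows centred in the ROI.

    Window sides are ``window_mm`` converted to samples/lines; steps are
    8 % of the window (min 1), i.e. 92 % overlap.  A window is retained when
    it lies fully inside the slice and its center pixel is inside the mask.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        raise ValueError("empty ROI mask")
    nz, nl = slice_shape
    wa = int(round(window_mm * 1e-3 / acq.axial_interval))
    wl = int(round(window_mm * 1e-3 / acq.lateral_pitch))
    if wa < 2 or wl < 1 or wa > nz or wl > nl:
        raise ValueError("ROI smaller than analysis window")
    sa = max(1, round((1.0 - OVERLAP) * wa))
    sl = max(1, round((1.0 - OVERLAP) * wl))
    rows = np.arange(0, nz - wa + 1, sa)
    cols = np.arange(0, nl - wl + 1, sl)
    ctr_r = rows + wa // 2
    ctr_c = cols + wl // 2
    keep = mask[np.ix_(ctr_r, ctr_c)]
    ij = np.argwhere(keep)
    if len(ij) == 0:
        raise ValueError("ROI smaller than analysis window")
    positions = np.column_stack([rows[ij[:, 0]], cols[ij[:, 1]]])
    return WindowGrid(window_axial=wa, window_lateral=wl,
                      step_axial=sa, step_lateral=sl,
                      cand_rows=rows, cand_cols=cols,
                      positions=positions, lattice_index=ij)


def _nfft_for(window_samples: int, pad_factor: int = PAD_FACTOR) -> int:
    return 1 << int(np.ceil(np.log2(pad_factor * window_samples)))


def _band(acq: AcquisitionSpec, nfft: int) -> tuple[np.ndarray, np.ndarray]:
    f = np.fft.rfftfreq(nfft, 1.0 / acq.sampling_frequency)
    m = (f >= acq.band_low) & (f <= acq.band_high)
    return f[m], m


def _window_power(rf: np.ndarray, rows: np.ndarray, cols: np.ndarray,
                  wa: int, wl: int, nfft: int,
                  band_mask: np.ndarray) -> np.ndarray:
    """Line-averaged Hann periodograms for windows at (rows, cols) origins."""
    taper = np.hanning(wa)
    n = len(rows)
    nf = int(band_mask.sum())
    out = np.empty((n, nf))
    chunk = max(1, (1 << 22) // max(1, wa * wl))
    ia = np.arange(wa)
    il = np.arange(wl)
    for s in range(0, n, chunk):
        r = rows[s:s + chunk]
        c = cols[s:s + chunk]
        w = rf[(r[:, None] + ia)[:, :, None], (c[:, None] + il)[:, None, :]]
        spec = np.fft.rfft(w * taper[None, :, None], n=nfft, axis=1)
        p = (spec.real**2 + spec.imag**2).mean(axis=2)
        out[s:s + chunk] = p[:, band_mask]
    return out


def _line_power_by_row(rf: np.ndarray, rows: np.ndarray, wa: int, nfft: int,
                       band_mask: np.ndarray) -> np.ndarray:
    """Per-(row, scan line) Hann periodograms on the band.

    Windows at 92 % overlap share their per-line segments laterally, so the
    expensive FFTs are done once per (depth row, line) and window averages
    are formed afterwards with cumulative sums.  Returns (n_rows, n_lines,
    n_band).
    """
    taper = np.hanning(wa)
    out = np.empty((len(rows), rf.shape[1], int(band_mask.sum())))
    for i, r in enumerate(rows):
        seg = rf[r:r + wa] * taper[:, None]
        spec = np.fft.rfft(seg, n=nfft, axis=0)
        out[i] = (spec.real**2 + spec.imag**2).T[:, band_mask]
    return out


def _window_average(pl: np.ndarray, cols: np.ndarray, wl: int) -> np.ndarray:
    """Average per-line powers over ``wl`` lines starting at each col.

    ``pl`` is (n_rows, n_lines, nf); returns (n_rows, n_cols, nf).
    """
    cs = np.concatenate([np.zeros_like(pl[:, :1]), np.cumsum(pl, axis=1)],
                        axis=1)
    return (cs[:, cols + wl] - cs[:, cols]) / wl


def _phantom_row_reference(phantom_rf, rows: np.ndarray,
                           wa: int, nfft: int,
                           band_mask: np.ndarray) -> np.ndarray:
    """Mean phantom power spectrum per depth row.

    ``phantom_rf`` is one frame or a sequence of independent frames.  The
    phantom is laterally homogeneous, so every lateral position at the same
    depth estimates the same reference; averaging across the full width and
    across frames suppresses phantom speckle noise (which would otherwise
    enter every tissue spectrum as a frozen depth-dependent error).
    """
    frames = [phantom_rf] if isinstance(phantom_rf, np.ndarray) \
        and phantom_rf.ndim == 2 else list(phantom_rf)
    acc = 0.0
    for frame in frames:
        pl = _line_power_by_row(np.asarray(frame, dtype=float), rows, wa,
                                nfft, band_mask)
        acc = acc + pl.mean(axis=1)
    return acc / len(frames)


class PhantomReference:
    """Phantom row-reference spectra with a per-(gate, FFT) cache.

    The same phantom serves every slice of every patient in a cohort; rows
    are computed on demand and memoized so repeated extractions do not redo
    the frame-averaged FFTs.
    """

    def __init__(self, frames) -> None:
        if isinstance(frames, np.ndarray) and frames.ndim == 2:
            frames = [frames]
        self.frames = [np.asarray(f, dtype=float) for f in frames]
        self._cache: dict = {}

    def rows(self, rows: np.ndarray, wa: int, nfft: int,
             band_mask: np.ndarray) -> np.ndarray:
        store = self._cache.setdefault((wa, nfft), {})
        missing = np.array([r for r in rows if r not in store], dtype=int)
        if missing.size:
            ref = _phantom_row_reference(self.frames, missing, wa, nfft,
                                         band_mask)
            for r, v in zip(missing, ref):
                store[int(r)] = v
        return np.array([store[int(r)] for r in rows])


def normalized_spectrum(window_rf: np.ndarray, phantom_rf_matched: np.ndarray,
                        acq: AcquisitionSpec,
                        pad_factor: int = PAD_FACTOR
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Phantom-normalized power spectrum of one window, in dB on the band.

    ``S(f) = 10 log10(P_tissue / P_phantom)`` with P the Hann-tapered,
    scan-line-averaged squared FFT magnitude.  The phantom window must have
    the same shape (same depth span and size).
    """
    window_rf = np.asarray(window_rf, dtype=float)
    phantom_rf_matched = np.asarray(phantom_rf_matched, dtype=float)
    if window_rf.shape != phantom_rf_matched.shape:
        raise ValueError("phantom window must match the tissue window shape")
    wa, wl = window_rf.shape
    nfft = _nfft_for(wa, pad_factor)
    f_band, band_mask = _band(acq, nfft)
    zero = np.zeros(1, dtype=np.intp)
    pt = _window_power(window_rf, zero, zero, wa, wl, nfft, band_mask)[0]
    pp = _window_power(phantom_rf_matched, zero, zero, wa, wl, nfft,
                       band_mask)[0]
    if np.any(pp <= 0.0):
        raise ValueError("phantom power is zero inside the analysis band")
    return f_band, 10.0 * np.log10(pt / pp)


def _linfit(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS slope/intercept of y against x along the last axis."""
    xm = x.mean()
    xc = x - xm
    denom = float(xc @ xc)
    slope = (y @ xc) / denom
    intercept = y.mean(axis=-1) - slope * xm
    return slope, intercept


def fit_mbf_ss_si(spectrum_db: np.ndarray, freq_hz: np.ndarray,
                  fc_hz: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Lizzi-Feleppa line fit: returns (MBF dB, SS dB/MHz, SI dB).

    Works on a single spectrum or a stack (windows on the first axis).
    """
    spectrum_db = np.asarray(spectrum_db, dtype=float)
    if not np.all(np.isfinite(spectrum_db)):
        raise ValueError("non-finite spectrum values")
    f_mhz = np.asarray(freq_hz, dtype=float) / 1e6
    if f_mhz.size < 3:
        raise ValueError("need at least 3 band frequencies")
    ss, si = _linfit(f_mhz, spectrum_db)
    mbf = ss * (fc_hz / 1e6) + si
    return mbf, ss, si


def estimate_asd_aac(spectrum_db: np.ndarray, freq_hz: np.ndarray,
                     acq: AcquisitionSpec, *,
                     reference_aac_db: float = AAC_REFERENCE_DB
                     ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Gaussian form-factor inversion: (ASD um, AAC dB, flagged).

    ln P_norm(f) is regressed on k^2 (k = 2 pi f / c).  Slope -> effective
    radius a = sqrt(max(0, -slope) / 0.827), ASD = 2 a, clipped to the
    display range and flagged when clipped or when the slope is non-physical
    (positive).  Intercept -> AAC in dB relative to the phantom concentration
    placed at ``reference_aac_db``.
    """
    spectrum_db = np.asarray(spectrum_db, dtype=float)
    if not np.all(np.isfinite(spectrum_db)):
        raise ValueError("non-finite spectrum values")
    k2 = (2.0 * np.pi * np.asarray(freq_hz, dtype=float)
          / acq.sound_speed) ** 2
    y = spectrum_db * _LN10_over_10
    slope, intercept = _linfit(k2, y)
    a = np.sqrt(np.maximum(0.0, -slope) / GAUSS_FF_CONST)
    asd = 2.0 * a * 1e6
    flagged = (slope >= 0) | (asd < ASD_RANGE_UM[0]) | (asd > ASD_RANGE_UM[1])
    asd = np.clip(asd, *ASD_RANGE_UM)
    aac = _10_over_LN10 * intercept + reference_aac_db
    return asd, aac, flagged


def spectral_autocorrelation(spectrum_linear: np.ndarray
                             ) -> np.ndarray:
    """Normalized biased autocorrelation of mean-removed spectra over lag.

    Input may be (nf,) or (n, nf); output has the same leading shape with
    lag (in frequency-bin units) on the last axis.  All-zero spectra return
    all-zero autocorrelations.
    """
    x = np.atleast_2d(np.asarray(spectrum_linear, dtype=float))
    x = x - x.mean(axis=-1, keepdims=True)
    nf = x.shape[-1]
    nfft = 1 << int(np.ceil(np.log2(2 * nf)))
    spec = np.fft.rfft(x, n=nfft, axis=-1)
    r = np.fft.irfft(spec.real**2 + spec.imag**2, n=nfft, axis=-1)[..., :nf]
    r /= nf
    r0 = r[..., 0:1].copy()
    good = r0[..., 0] > 1e-300
    r[good] /= r0[good]
    r[~good] = 0.0
    if spectrum_linear.ndim == 1:
        return r[0]
    return r


def _sas_lag_indices(df: float, nf: int, acq: AcquisitionSpec
                     ) -> tuple[int, int]:
    lag_min = acq.sound_speed / (2.0 * SAS_RANGE_MM[1] * 1e-3)
    lag_max = acq.sound_speed / (2.0 * SAS_RANGE_MM[0] * 1e-3)
    if (nf - 1) * df < lag_min:
        raise ValueError("band narrower than the minimum detectable lag")
    lo = max(1, int(np.ceil(lag_min / df)))
    hi = min(nf - 2, int(np.floor(lag_max / df)))
    return lo, hi


def estimate_sas(spectrum_linear: np.ndarray, freq_hz: np.ndarray,
                 acq: AcquisitionSpec, *,
                 prominence: float = SAS_PROMINENCE
                 ) -> tuple[np.ndarray, np.ndarray]:
    """Spacing among scatterers from the spectral autocorrelation, in mm.

    The most prominent local maximum of the normalized autocorrelation whose
    lag maps into the admissible spacing range gives SAS = c / (2 * lag),
    with parabolic lag refinement.  Windows without a peak above
    ``prominence`` fall back to the upper clip (2.5 mm) and are flagged.
    """
    spec = np.asarray(spectrum_linear, dtype=float)
    single = spec.ndim == 1
    f = np.asarray(freq_hz, dtype=float)
    df = float(f[1] - f[0])
    r = np.atleast_2d(spectral_autocorrelation(spec))
    sas, flagged = _sas_peaks(r, df, acq, prominence)
    if single:
        return sas[0], flagged[0]
    return sas, flagged


def _sas_peaks(r: np.ndarray, df: float, acq: AcquisitionSpec,
               prominence: float = SAS_PROMINENCE
               ) -> tuple[np.ndarray, np.ndarray]:
    """Most prominent admissible autocorrelation peak -> spacing per row."""
    nf = r.shape[-1]
    lo, hi = _sas_lag_indices(df, nf, acq)
    sas = np.full(r.shape[0], SAS_RANGE_MM[1])
    flagged = np.ones(r.shape[0], dtype=bool)
    seg = r[:, lo:hi + 1]
    is_peak = (seg > r[:, lo - 1:hi]) & (seg >= r[:, lo + 1:hi + 2]) \
        & (seg >= prominence)
    cand = np.where(is_peak, seg, -np.inf)
    best = np.argmax(cand, axis=1)
    has = np.isfinite(cand[np.arange(len(best)), best])
    for i in np.nonzero(has)[0]:
        l = lo + best[i]
        rm, r0_, rp = r[i, l - 1], r[i, l], r[i, l + 1]
        denom = rm - 2.0 * r0_ + rp
        delta = 0.5 * (rm - rp) / denom if denom != 0 else 0.0
        lag_hz = (l + np.clip(delta, -0.5, 0.5)) * df
        val = acq.sound_speed / (2.0 * lag_hz) * 1e3
        inside = SAS_RANGE_MM[0] <= val <= SAS_RANGE_MM[1]
        sas[i] = float(np.clip(val, *SAS_RANGE_MM))
        flagged[i] = not inside
    return sas, flagged


def _box_mean_lattice(values: np.ndarray, index: np.ndarray,
                      shape: tuple[int, int], half: int) -> np.ndarray:
    """Mean of per-window vectors over a (2*half+1)^2 lattice neighbourhood.

    ``values`` is (n, L) with each row living at lattice cell ``index[i]``;
    cells without a window are ignored.  Integral images keep this O(R*C*L).
    """
    if half <= 0:
        return values
    nr, nc = shape
    filled = np.zeros((nr, nc, values.shape[1]))
    cnt = np.zeros((nr, nc))
    filled[index[:, 0], index[:, 1]] = values
    cnt[index[:, 0], index[:, 1]] = 1.0
    s = np.pad(filled, ((1, 0), (1, 0), (0, 0))).cumsum(0).cumsum(1)
    c = np.pad(cnt, ((1, 0), (1, 0))).cumsum(0).cumsum(1)
    r0 = np.clip(index[:, 0] - half, 0, nr)
    r1 = np.clip(index[:, 0] + half + 1, 0, nr)
    c0 = np.clip(index[:, 1] - half, 0, nc)
    c1 = np.clip(index[:, 1] + half + 1, 0, nc)
    tot = s[r1, c1] - s[r0, c1] - s[r1, c0] + s[r0, c0]
    n = c[r1, c1] - c[r0, c1] - c[r1, c0] + c[r0, c0]
    return tot / np.maximum(n, 1.0)[:, None]


def estimate_ace(spectra_db: np.ndarray, row_of_window: np.ndarray,
                 row_depth_cm: np.ndarray, freq_hz: np.ndarray) -> float:
    """Attenuation coefficient estimate, dB cm^-1 MHz^-1, one per slice.

    Spectral-difference method: per band frequency, the mean normalized
    log-spectrum of each window row is regressed against the row depth to get
    a decay rate beta(f) in dB/cm; the slope of beta against f (MHz), halved
    for two-way propagation, is the ACE.
    """
    rows = np.unique(row_of_window)
    if len(rows) < 3:
        raise ValueError("ROI must span >= 3 window rows in depth")
    depth = np.empty(len(rows))
    mean_s = np.empty((len(rows), spectra_db.shape[-1]))
    row_depth_cm = np.asarray(row_depth_cm, dtype=float)
    for i, rr in enumerate(rows):
        sel = row_of_window == rr
        mean_s[i] = spectra_db[sel].mean(axis=0)
        depth[i] = row_depth_cm[rr]
    beta, _ = _linfit_x(depth, mean_s)          # dB/cm per frequency
    dslope, _ = _linfit(np.asarray(freq_hz) / 1e6, beta)
    return float(-dslope / 2.0)


def _linfit_x(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """OLS of y's first axis against x: y (n, m) -> slope/intercept (m,)."""
    xm = x.mean()
    xc = x - xm
    denom = float(xc @ xc)
    slope = (xc @ y) / denom
    intercept = y.mean(axis=0) - slope * xm
    return slope, intercept


@dataclass
class SliceFeatures:
    """Per-slice extraction result: maps, window estimates and aggregates."""

    grid: WindowGrid
    freq_hz: np.ndarray
    ace: float
    window_values: dict[str, np.ndarray]
    maps: dict[str, np.ndarray]
    window_means: dict[str, float]
    aggregates: dict[str, float]
    flags: dict[str, int] = field(default_factory=dict)

    @property
    def n_windows(self) -> int:
        return self.grid.n_windows

    @property
    def area(self) -> float:
        """Slice weight for cross-slice aggregation (in-ROI window count)."""
        return float(self.grid.n_windows)


def _to_map(grid: WindowGrid, values: np.ndarray) -> np.ndarray:
    m = np.full(grid.map_shape(), np.nan)
    m[grid.lattice_index[:, 0], grid.lattice_index[:, 1]] = values
    return m


def extract_slice(rf: np.ndarray, mask: np.ndarray, phantom_rf,
                  acq: AcquisitionSpec, *,
                  window_mm: float = WINDOW_MM,
                  reference_aac_db: float = AAC_REFERENCE_DB,
                  sas_gate_mm: float = SAS_GATE_MM) -> SliceFeatures:
    """Run the full spectral stage on one slice.

    Returns per-window estimates, parametric-map lattices for the six mapped
    parameters, the per-slice ACE scalar, and ROI-aggregate estimates
    (fits to the window-averaged spectrum / window-averaged autocorrelation)
    used for parameter-recovery checks.
    """
    rf = np.asarray(rf, dtype=float)
    phantom = phantom_rf if isinstance(phantom_rf, PhantomReference) \
        else PhantomReference(phantom_rf)
    grid = build_window_grid(rf.shape, mask, acq, window_mm)
    wa, wl = grid.window_axial, grid.window_lateral
    nfft = _nfft_for(wa)
    f_band, band_mask = _band(acq, nfft)
    dz_cm = acq.axial_interval * 100.0

    rows = grid.positions[:, 0]
    cols = grid.positions[:, 1]
    uniq_rows, row_inv = np.unique(rows, return_inverse=True)
    uniq_cols, col_inv = np.unique(cols, return_inverse=True)
    pl = _line_power_by_row(rf, uniq_rows, wa, nfft, band_mask)
    p_t = _window_average(pl, uniq_cols, wl)[row_inv, col_inv]
    ref = phantom.rows(uniq_rows, wa, nfft, band_mask)
    if np.any(ref <= 0.0):
        raise ValueError("phantom power is zero inside the analysis band")
    s_db = 10.0 * np.log10(p_t / ref[row_inv])

    depth_cm = (uniq_rows + wa / 2.0) * dz_cm
    ace = estimate_ace(s_db, row_inv, depth_cm, f_band)

    # attenuation compensation: +2 * ACE * f * z dB per window
    f_mhz = f_band / 1e6
    s_comp = s_db + 2.0 * ace * f_mhz[None, :] * depth_cm[row_inv][:, None]

    mbf, ss, si = fit_mbf_ss_si(s_comp, f_band, acq.center_frequency)
    asd, aac, asd_flag = estimate_asd_aac(
        s_comp, f_band, acq, reference_aac_db=reference_aac_db)

    # --- SAS on a dedicated longer gate centred on each window ------------
    nz, nl = rf.shape
    ga = min(nz, int(round(sas_gate_mm * 1e-3 / acq.axial_interval)))
    gl = min(nl, 2 * wl)
    ctr = grid.centers()
    g_rows = np.clip(ctr[:, 0] - ga // 2, 0, nz - ga)
    g_cols = np.clip(ctr[:, 1] - gl // 2, 0, nl - gl)
    nfft_g = _nfft_for(ga, 2)
    fg_band, g_mask = _band(acq, nfft_g)
    g_uniq, g_inv = np.unique(g_rows, return_inverse=True)
    gc_uniq, gc_inv = np.unique(g_cols, return_inverse=True)
    pl_g = _line_power_by_row(rf, g_uniq, ga, nfft_g, g_mask)
    p_g = _window_average(pl_g, gc_uniq, gl)[g_inv, gc_inv]
    ref_g = phantom.rows(g_uniq, ga, nfft_g, g_mask)
    sg_db = 10.0 * np.log10(p_g / np.maximum(ref_g[g_inv], 1e-300))
    g_depth_cm = (g_uniq + ga / 2.0) * dz_cm
    sg_db = sg_db + 2.0 * ace * (fg_band / 1e6)[None, :] \
        * g_depth_cm[g_inv][:, None]
    # remove the residual spectral trend so broadband slope does not mask
    # the periodicity
    sl_, ic_ = _linfit(fg_band / 1e6, sg_db)
    sg_detr = sg_db - (sl_[:, None] * (fg_band / 1e6)[None, :] + ic_[:, None])
    sg_lin = 10.0 ** (sg_detr / 10.0)
    # per-window spacing: autocorrelations averaged over a small spatial
    # neighbourhood before peak-picking (a single gate holds only a few
    # regular-spacing periods, so its autocorrelation is speckle-dominated;
    # the ripple lag is shared by neighbouring gates while speckle is not)
    r_win = spectral_autocorrelation(sg_lin)
    r_sm = _box_mean_lattice(r_win, grid.lattice_index, grid.map_shape(),
                             SAS_SMOOTH_HALF)
    df_g = float(fg_band[1] - fg_band[0])
    sas, sas_flag = _sas_peaks(r_sm, df_g, acq)

    window_values = {"MBF": mbf, "SS": ss, "SI": si, "AAC": aac,
                     "ASD": asd, "SAS": sas}
    maps = {k: _to_map(grid, v) for k, v in window_values.items()}
    window_means = {k: float(v.mean()) for k, v in window_values.items()}

    # ROI-aggregate estimates: MBF/SS/SI from the window-averaged compensated
    # spectrum; ASD/AAC from a joint fit over all (window, frequency) pairs
    # with an explicit attenuation term, ln P = b + s k^2 - q f z, so that
    # the form-factor slope is estimated orthogonally to any residual
    # depth-dependent tilt instead of inheriting the ACE estimate's error.
    s_mean = s_comp.mean(axis=0)
    agg_mbf, agg_ss, agg_si = fit_mbf_ss_si(s_mean, f_band,
                                            acq.center_frequency)
    agg_asd, agg_aac = _joint_asd_aac(
        s_db, f_band, depth_cm[row_inv], acq,
        reference_aac_db=reference_aac_db)
    # SAS aggregate from the window-averaged autocorrelation: spacing jitter
    # keeps the ripple coherent within a gate but not across the ensemble-
    # averaged spectrum, so autocorrelations are averaged, not spectra.
    r_mean = r_win.mean(axis=0)
    agg_sas, agg_sas_flag = _sas_from_autocorr(r_mean, fg_band, acq)

    aggregates = {"MBF": float(agg_mbf), "SS": float(agg_ss),
                  "SI": float(agg_si), "ASD": float(agg_asd),
                  "AAC": float(agg_aac), "SAS": agg_sas, "ACE": ace}
    flags = {"ASD_clipped": int(asd_flag.sum()),
             "SAS_fallback": int(sas_flag.sum()),
             "SAS_aggregate_fallback": int(agg_sas_flag)}
    return SliceFeatures(grid=grid, freq_hz=f_band, ace=ace,
                         window_values=window_values, maps=maps,
                         window_means=window_means, aggregates=aggregates,
                         flags=flags)


def _joint_asd_aac(s_db: np.ndarray, freq_hz: np.ndarray,
                   window_depth_cm: np.ndarray, acq: AcquisitionSpec, *,
                   reference_aac_db: float = AAC_REFERENCE_DB
                   ) -> tuple[float, float]:
    """ROI-aggregate ASD/AAC by a joint fit with an attenuation term.

    Model over all (window, frequency) samples of the raw normalized
    log-spectrum: ln P = b + s k^2 - q (f z); depth variation across the ROI
    identifies the attenuation tilt, leaving the k^2 coefficient an
    (orthogonalized) estimate of the Gaussian form-factor slope.
    """
    f = np.asarray(freq_hz, dtype=float)
    k2 = (2.0 * np.pi * f / acq.sound_speed) ** 2
    n_w = s_db.shape[0]
    y = (s_db * _LN10_over_10).ravel()
    x1 = np.tile(k2, n_w)
    x2 = (np.asarray(window_depth_cm)[:, None] * (f / 1e6)[None, :]).ravel()
    a = np.column_stack([np.ones_like(x1), x1, x2])
    coef, *_ = np.linalg.lstsq(a, y, rcond=None)
    b, s = coef[0], coef[1]
    asd = float(np.clip(
        2e6 * np.sqrt(max(0.0, -s) / GAUSS_FF_CONST), *ASD_RANGE_UM))
    aac = float(_10_over_LN10 * b + reference_aac_db)
    return asd, aac


def _sas_from_autocorr(r: np.ndarray, freq_hz: np.ndarray,
                       acq: AcquisitionSpec,
                       prominence: float = SAS_PROMINENCE
                       ) -> tuple[float, bool]:
    """Peak-pick an already-averaged normalized autocorrelation."""
    df = float(freq_hz[1] - freq_hz[0])
    nf = r.shape[-1]
    lo, hi = _sas_lag_indices(df, nf, acq)
    seg = r[lo:hi + 1]
    is_peak = (seg > r[lo - 1:hi]) & (seg >= r[lo + 1:hi + 2]) \
        & (seg >= prominence)
    if not is_peak.any():
        return SAS_RANGE_MM[1], True
    l = lo + int(np.argmax(np.where(is_peak, seg, -np.inf)))
    rm, r0_, rp = r[l - 1], r[l], r[l + 1]
    denom = rm - 2.0 * r0_ + rp
    delta = 0.5 * (rm - rp) / denom if denom != 0 else 0.0
    lag_hz = (l + float(np.clip(delta, -0.5, 0.5))) * df
    val = acq.sound_speed / (2.0 * lag_hz) * 1e3
    inside = SAS_RANGE_MM[0] <= val <= SAS_RANGE_MM[1]
    return float(np.clip(val, *SAS_RANGE_MM)), not inside
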