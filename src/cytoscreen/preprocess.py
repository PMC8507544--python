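"""Spectral pre-processing: cosmic-ray removal, EMSC, denoising, quality culling.

The pipeline applied to every acquired cell spectrum:

1. **Cosmic-ray removal** — spikes are found against the closest-matching
   spectrum in the dataset and replaced with that spectrum's (scaled) values,
   avoiding the double-acquisition approach that halves throughput.
2. **EMSC** (extended multiplicative signal correction) — each raw spectrum
   ``X0`` is decomposed by ordinary least squares into a cell reference ``R``
   weighted ``cr``, a substrate (glass) reference ``B`` weighted ``cb`` and an
   N-order polynomial baseline; the corrected spectrum is
   ``X = (X0 - cb*B - sum_m cm*Pm) / cr``, normalised to the reference scale.
3. **Savitzky-Golay denoising** (order 3, window 7 by default).
4. **Quality culling** — spectra whose Pearson correlation with the cell
   reference falls below 0.99 are removed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage
import scipy.signal

from .spectral_core import Spectrum, SpectrumSet, WavenumberAxis, pearson_rows

__all__ = [
    "EMSCResult",
    "QualityReport",
    "CosmicRayReport",
    "CollinearityError",
    "DegenerateFitError",
    "remove_cosmic_rays",
    "build_reference",
    "build_substrate_reference",
    "emsc_correct",
    "emsc_correct_set",
    "savitzky_golay",
    "quality_cull",
]


class CollinearityError(ValueError):
    """EMSC design matrix components are (numerically) linearly dependent."""


class DegenerateFitError(ValueError):
    """EMSC returned a non-positive or vanishing reference weight."""


@dataclass
class EMSCResult:
    corrected: Spectrum
    cr: float
    cb: float
    cm: np.ndarray
    residual_norm: float


@dataclass
class QualityReport:
    r: np.ndarray  # per-spectrum Pearson r vs the reference
    retained: np.ndarray  # boolean flags

    @property
    def retention_fraction(self) -> float:
        return float(np.mean(self.retained)) if len(self.retained) else 0.0


@dataclass
class CosmicRayReport:
    flagged: list[list[int]] = field(default_factory=list)  # per spectrum
    matched_id: list[str | None] = field(default_factory=list)

    @property
    def n_flagged_channels(self) -> int:
        return sum(len(f) for f in self.flagged)


# ---------------------------------------------------------------------------
# Cosmic-ray removal


def _match_model(
    X: np.ndarray,
    despiked: np.ndarray,
    smooth: np.ndarray,
    i: int,
    good: np.ndarray,
    P: np.ndarray,
    shortlist: int = 40,
    n_consensus: int = 7,
    extra: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    """Reference model for spectrum ``i`` built from its closest matches.

    The most correlated candidates (ranked on a despiked proxy, so a shared
    spike cannot inflate the correlation) are each fitted to ``i`` as scale
    plus low-order polynomial; the candidates with the smallest robust
    residual spread — i.e. compatible component weights, not just shared
    structure — form a channel-wise median model.  The median over several
    independently recorded spectra is immune to any single match's own
    cosmic rays.  Detection uses denoised (Savitzky-Golay) match columns so
    the reference carries no per-channel noise of its own; returns the
    detection model, the raw-match replacement values, the single best
    match's index, and the per-channel model-uncertainty estimate.
    """
    others = np.delete(np.arange(X.shape[0]), i)
    r = pearson_rows(despiked[others][:, good], despiked[i, good])
    top = others[np.argsort(-r, kind="stable")[:shortlist]]
    # rank candidates by the k-th largest |residual|: large enough k to skip
    # past this spectrum's own spikes, small enough to feel a band-height
    # mismatch (a poor relative cell/substrate weight) at sharp peaks
    k_order = 2 * 3 + 1
    fits = []
    for j in top:
        model = _fit_match(X[i], smooth[j], P, good, extra,
                           x_d=despiked[i], m_d=despiked[j])
        resid = np.abs(X[i, good] - model[good])
        k = min(k_order, len(resid))
        score = float(np.partition(resid, -k)[-k])
        fits.append((score, int(j), model))
    fits.sort(key=lambda t: t[0])
    chosen = np.stack([m for _, _, m in fits[:n_consensus]])
    model = np.median(chosen, axis=0)
    # channel-wise disagreement of the candidate fits = model uncertainty:
    # large where band-height mismatch makes any single match unreliable,
    # small at a genuine spike (every clean, denoised match agrees there)
    spread = (1.4826 * np.median(np.abs(chosen - model), axis=0)
              if len(chosen) > 1 else np.zeros_like(model))
    # replacement values come from the raw matches (a median over the
    # consensus protects against any one match's own spike), so the repair
    # inserts genuinely recorded intensities, not smoothed ones
    raw = np.stack([_fit_match(X[i], X[j], P, good, extra,
                               x_d=despiked[i], m_d=despiked[j])
                    for _, j, _ in fits[:n_consensus]])
    replacement = np.median(raw, axis=0)
    return model, replacement, fits[0][1], spread


def _noise_law_sigma(resid: np.ndarray, counts: np.ndarray, good: np.ndarray,
                     n_bins: int = 10) -> np.ndarray:
    """Per-channel noise sigma from the CCD noise law ``sigma^2 = a + b*counts``.

    Read noise contributes a constant floor and shot noise grows linearly
    with the signal, so binning channels by intensity and robustly measuring
    the residual spread per bin recovers the law without knowing the camera
    calibration.  This captures the sharp sigma increase on strong, narrow
    bands that any windowed estimate smears out.
    """
    x = counts[good]
    r = resid[good]
    order = np.argsort(x)
    bins = np.array_split(order, n_bins)
    xs, s2 = [], []
    for b in bins:
        if len(b) < 8:
            continue
        rb = r[b]
        mad = 1.4826 * float(np.median(np.abs(rb - np.median(rb))))
        xs.append(float(np.median(x[b])))
        s2.append(mad * mad)
    if len(xs) < 2:
        mad = 1.4826 * float(np.median(np.abs(r - np.median(r)))) or 1e-12
        return np.full_like(resid, mad)
    A = np.column_stack([np.ones(len(xs)), xs])
    coef, *_ = np.linalg.lstsq(A, np.asarray(s2), rcond=None)
    a, b = float(coef[0]), float(coef[1])
    b = max(b, 0.0)
    var = a + b * np.clip(counts, 0.0, None)
    floor = 0.25 * float(np.median(s2))
    return np.sqrt(np.maximum(var, floor))


def _rolling_robust_sigma(resid: np.ndarray, window: int = 25) -> np.ndarray:
    """Per-channel MAD-based sigma of the residual over a centred window.

    A channel-wise scale adapts to shot noise (stronger on intense bands) and
    to smooth match mismatch around peaks; the window is much wider than a
    cosmic ray, so spikes barely move their own local MAD.  A floor of half
    the global robust sigma guards against degenerate flat stretches.
    """
    med = scipy.ndimage.median_filter(resid, size=window, mode="nearest")
    mad = scipy.ndimage.median_filter(np.abs(resid - med), size=window, mode="nearest")
    sigma = 1.4826 * mad
    global_sigma = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if global_sigma <= 0:
        global_sigma = float(np.std(resid)) or 1e-12
    return np.maximum(sigma, 0.5 * global_sigma)


def _fit_match(
    x: np.ndarray, m: np.ndarray, P: np.ndarray, good: np.ndarray,
    extra: np.ndarray | None = None,
    x_d: np.ndarray | None = None, m_d: np.ndarray | None = None,
) -> np.ndarray:
    """Least-squares fit of the matched spectrum plus a smooth polynomial
    correction to ``x`` over the ``good`` channels; returns the fitted model
    on all channels.

    The polynomial absorbs the smooth baseline/substrate mismatch between a
    spectrum and its match, so the residual carries only narrow features
    (noise and cosmic rays).  ``extra`` (the dataset's robust median
    spectrum, when available) additionally absorbs a band-height mismatch
    between the pair — two cells recorded at different focus share shape but
    not the cell-to-background weight ratio.
    """
    cols = [m] if extra is None else [m, extra]
    D = np.column_stack(cols + [P])
    if x_d is not None and m_d is not None:
        # robust initialisation on the despiked pair: a gross spike in either
        # spectrum would otherwise collapse the least-squares scale (cheaper
        # for the fit to drop the match than to absorb a huge outlier)
        cols_d = [m_d] if extra is None else [m_d, extra]
        Dd = np.column_stack(cols_d + [P])
        coef, *_ = np.linalg.lstsq(Dd[good], x_d[good], rcond=None)
    else:
        coef, *_ = np.linalg.lstsq(D[good], x[good], rcond=None)
    resid = x[good] - (D @ coef)[good]
    mad = 1.4826 * float(np.median(np.abs(resid - np.median(resid))))
    if mad > 0:
        # final fit on raw data without gross outliers; the threshold sits
        # far above band-height mismatch so ordinary spectral disagreement
        # still steers the fit
        keep = np.abs(resid) <= 25.0 * mad
        if keep.sum() >= D.shape[1] + 2:
            sub = np.flatnonzero(good)[keep]
            coef, *_ = np.linalg.lstsq(D[sub], x[sub], rcond=None)
    return D @ coef


def remove_cosmic_rays(
    ss: SpectrumSet,
    k_sigma: float = 8.0,
    max_width: int = 3,
    baseline_order: int = 5,
) -> tuple[SpectrumSet, CosmicRayReport]:
    """Detect and repair cosmic-ray spikes by matched-spectrum substitution.

    For each spectrum the closest-matching other spectrum (highest Pearson r
    on non-suspect channels) is fitted by least squares — a scale factor plus
    a low-order polynomial absorbing the smooth baseline difference between
    the pair.  Channels whose residual exceeds ``k_sigma`` times a MAD-based
    robust sigma, in contiguous runs no wider than ``max_width`` channels,
    are flagged and replaced by the fitted match.  Two detection passes are
    run; the operation is idempotent on clean data and never alters
    unflagged channels.
    """
    if len(ss) < 2:
        raise ValueError(
            "cosmic-ray removal needs >= 2 spectra (enable the median-filter "
            "fallback in the run configuration for single spectra)"
        )
    X = ss.matrix
    n, p = X.shape
    report = CosmicRayReport()
    out = X.copy()
    P = _legendre_basis(ss.axis, baseline_order)
    # match selection runs on a median-filtered proxy: two spectra that
    # happen to share a spike channel would otherwise correlate best of all
    despiked = scipy.ndimage.median_filter(X, size=(1, 2 * max_width + 1),
                                           mode="nearest")
    # denoised matches for detection: a match's shot/read noise would other-
    # wise enter the detection threshold at full strength.  Smoothing smears
    # a match's own spikes over its neighbours, which only the consensus
    # median can discard — with too few spectra for a consensus, raw columns
    # are the safer reference
    smooth = (scipy.signal.savgol_filter(X, 7, 3, axis=1, mode="interp")
              if n >= 6 else X)
    # a cohort-median column lets the fit adjust overall band height: the
    # spectrum with the most extreme cell weight has no close match, but its
    # mismatch lies along the shared signature direction
    extra = np.median(smooth, axis=0) if n >= 6 else None


    for i in range(n):
        suspect = np.zeros(p, dtype=bool)
        match = None
        model = None
        for _pass in range(2):
            good = ~suspect
            if good.sum() < baseline_order + 3:
                break
            model, replacement, match, spread = _match_model(
                X, despiked, smooth, i, good, P, extra=extra)
            resid = X[i] - model
            noise = np.maximum(_rolling_robust_sigma(resid),
                               _noise_law_sigma(resid, np.clip(model, 0, None), good))
            # the median of the consensus errs less than its members disagree;
            # 0.6 ~ the median-vs-member error ratio for a handful of fits
            sigma = np.hypot(noise, 0.6 * spread)
            # one-sided: cosmic rays only ever add charge
            new_suspect = resid > k_sigma * sigma
            new_suspect = _prune_wide_runs(new_suspect, max_width)
            # flags accumulate: the second pass refines the model with the
            # first pass's spikes masked to uncover any it hid, it does not
            # re-litigate channels already identified
            new_suspect |= suspect
            if np.array_equal(new_suspect, suspect):
                break
            suspect = new_suspect

        flagged = np.flatnonzero(suspect)
        if len(flagged) and match is not None:
            out[i, flagged] = replacement[flagged]
            report.flagged.append(flagged.tolist())
            report.matched_id.append(ss.ids[match])
        else:
            report.flagged.append([])
            report.matched_id.append(None)

    return ss.with_matrix(out), report


def _prune_wide_runs(mask: np.ndarray, max_width: int) -> np.ndarray:
    """Unflag contiguous runs wider than ``max_width`` (not cosmic-ray-like)."""
    out = mask.copy()
    i = 0
    p = len(mask)
    while i < p:
        if out[i]:
            j = i
            while j < p and out[j]:
                j += 1
            if j - i > max_width:
                out[i:j] = False
            i = j
        else:
            i += 1
    return out


# ---------------------------------------------------------------------------
# Reference construction


def build_reference(ss: SpectrumSet, k: int = 50, rank: str = "median_r") -> Spectrum:
    """Mean of the ``k`` highest-quality spectra, with no smoothing applied.

    Quality is ranked by Pearson correlation against the dataset's
    channel-wise median spectrum (robust to spikes and outliers); an
    alternative signal-to-noise ranking is available with ``rank="snr"``.
    """
    if len(ss) < k:
        raise ValueError(f"need at least k={k} spectra, have {len(ss)}")
    if rank == "median_r":
        median = np.median(ss.matrix, axis=0)
        score = pearson_rows(ss.matrix, median)
    elif rank == "snr":
        smooth = scipy.signal.savgol_filter(ss.matrix, 9, 3, axis=1)
        noise_sd = np.std(ss.matrix - smooth, axis=1)
        score = np.ptp(smooth, axis=1) / np.where(noise_sd > 0, noise_sd, np.inf)
    else:
        raise ValueError(f"unknown rank {rank!r}")
    top = np.argsort(-score, kind="stable")[:k]
    return Spectrum(ss.axis, ss.matrix[top].mean(axis=0), id=f"reference_top{k}")


def build_substrate_reference(glass: SpectrumSet, window: int = 9, order: int = 3) -> Spectrum:
    """Channel-wise mean of the substrate spectra, Savitzky-Golay smoothed
    (order 3, window 9 by default)."""
    if len(glass) < 1:
        raise ValueError("need at least one substrate spectrum")
    mean = glass.matrix.mean(axis=0)
    smoothed = scipy.signal.savgol_filter(mean, window_length=window, polyorder=order,
                                          mode="interp")
    return Spectrum(glass.axis, smoothed, id="substrate_reference")


# ---------------------------------------------------------------------------
# EMSC


def _legendre_basis(axis: WavenumberAxis, order: int) -> np.ndarray:
    """Orthogonal (Legendre) polynomial columns on the axis mapped to [-1, 1]."""
    t = np.interp(axis.values, (axis.values[0], axis.values[-1]), (-1.0, 1.0))
    return np.column_stack(
        [np.polynomial.legendre.Legendre.basis(m)(t) for m in range(order + 1)]
    )


def emsc_correct(
    x0: Spectrum,
    ref: Spectrum,
    substrate: Spectrum | None = None,
    order: int = 5,
    cr_min: float = 1e-6,
    cond_max: float = 1e10,
) -> EMSCResult:
    """Extended multiplicative signal correction of one spectrum.

    Solves ``X0 ≈ cr*R + cb*B + sum_{m=0..N} cm*Pm`` by ordinary least
    squares, with ``Pm`` a Legendre basis on the axis rescaled to [-1, 1],
    and returns ``X = (X0 - cb*B - sum cm*Pm) / cr`` — baseline and substrate
    removed, intensity normalised to the reference scale.  ``cb`` is fixed at
    0 when no substrate is given (flat-background substrates such as
    Raman-grade CaF2 need none).
    """
    if x0.axis != ref.axis or (substrate is not None and substrate.axis != x0.axis):
        raise ValueError("spectrum, reference and substrate must share one axis")
    P = _legendre_basis(x0.axis, order)
    cols = [ref.intensities]
    if substrate is not None:
        cols.append(substrate.intensities)
    D = np.column_stack(cols + [P])

    norms = np.linalg.norm(D, axis=0)
    if np.any(norms == 0):
        raise CollinearityError("a zero component (constant-zero reference?) in the EMSC design")
    cond = np.linalg.cond(D / norms)
    if cond > cond_max:
        raise CollinearityError(_diagnose_collinearity(ref, substrate, P, cond))

    coef, *_ = np.linalg.lstsq(D, x0.intensities, rcond=None)
    cr = float(coef[0])
    if substrate is not None:
        cb = float(coef[1])
        cm = np.asarray(coef[2:], dtype=float)
        background = cb * substrate.intensities + P @ cm
    else:
        cb = 0.0
        cm = np.asarray(coef[1:], dtype=float)
        background = P @ cm
    residual = x0.intensities - (cr * ref.intensities + background)
    if cr <= cr_min:
        raise DegenerateFitError(
            f"EMSC reference weight cr={cr:.3g} <= {cr_min}; spectrum does not "
            "resemble the reference (negative or vanishing fit)"
        )
    corrected = (x0.intensities - background) / cr
    return EMSCResult(
        corrected=Spectrum(x0.axis, corrected, id=x0.id),
        cr=cr,
        cb=cb,
        cm=cm,
        residual_norm=float(np.linalg.norm(residual)),
    )


def _diagnose_collinearity(
    ref: Spectrum, substrate: Spectrum | None, P: np.ndarray, cond: float
) -> str:
    def rel_resid(target: np.ndarray, basis: np.ndarray) -> float:
        coef, *_ = np.linalg.lstsq(basis, target, rcond=None)
        return float(np.linalg.norm(target - basis @ coef) / (np.linalg.norm(target) or 1.0))

    if substrate is not None:
        onto = np.column_stack([ref.intensities, P])
        if rel_resid(substrate.intensities, onto) < 1e-6:
            return (
                f"EMSC design ill-conditioned (cond={cond:.2g}): the substrate "
                "spectrum is collinear with the reference/polynomial components"
            )
    if rel_resid(ref.intensities, P) < 1e-6:
        return (
            f"EMSC design ill-conditioned (cond={cond:.2g}): the reference "
            "spectrum lies in the polynomial-baseline space"
        )
    return f"EMSC design ill-conditioned (condition number {cond:.2g})"


def emsc_correct_set(
    ss: SpectrumSet,
    ref: Spectrum,
    substrate: Spectrum | None = None,
    order: int = 5,
) -> tuple[SpectrumSet, list[EMSCResult]]:
    """EMSC-correct every spectrum in a set (shared design factorisation)."""
    results = []
    out = np.empty_like(ss.matrix)
    for i in range(len(ss)):
        res = emsc_correct(ss.spectrum(i), ref, substrate, order=order)
        results.append(res)
        out[i] = res.corrected.intensities
    corrected = ss.with_matrix(out)
    for m, res in zip(corrected.meta, results):
        m["emsc_cr"] = res.cr
        m["emsc_cb"] = res.cb
    return corrected, results


# ---------------------------------------------------------------------------
# Denoising and quality culling


def savitzky_golay(s: Spectrum, window: int = 7, order: int = 3) -> Spectrum:
    """Savitzky-Golay smoothing: centred local least-squares polynomial fits.

    Edge channels are handled by fitting the polynomial on the truncated
    window and evaluating it at the edge positions.
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window <= order:
        raise ValueError("window must exceed the polynomial order")
    if len(s.axis) < window:
        raise ValueError("spectrum shorter than the smoothing window")
    sm = scipy.signal.savgol_filter(s.intensities, window_length=window,
                                    polyorder=order, mode="interp")
    return Spectrum(s.axis, sm, id=s.id)


def savitzky_golay_set(ss: SpectrumSet, window: int = 7, order: int = 3) -> SpectrumSet:
    if window % 2 == 0 or window <= order or ss.n_channels < window:
        raise ValueError("invalid Savitzky-Golay parameters for this dataset")
    sm = scipy.signal.savgol_filter(ss.matrix, window_length=window, polyorder=order,
                                    axis=1, mode="interp")
    return ss.with_matrix(sm)


def quality_cull(
    ss: SpectrumSet, ref: Spectrum, threshold: float = 0.99
) -> tuple[SpectrumSet, QualityReport]:
    """Remove spectra whose Pearson correlation with the reference is below
    ``threshold`` (the boundary value is retained)."""
    if ss.axis != ref.axis:
        raise ValueError("dataset and reference must share one axis")
    r = pearson_rows(ss.matrix, ref.intensities)
    retained = r >= threshold
    report = QualityReport(r=r, retained=retained)
    return ss.subset(np.flatnonzero(retained)), report
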