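"""Image-level preprocessing: CTF model and phase-flip correction, binning,
box handling, band-pass filtering and normalization.

The contrast transfer function is the standard weak-phase-object model

    CTF(f) = -[ sqrt(1 - A^2) sin(chi(f)) + A cos(chi(f)) ],
    chi(f) = pi lambda dz f^2 - (pi/2) Cs lambda^3 f^4,

with underfocus dz positive, amplitude contrast fraction A, and the
relativistic electron wavelength lambda at the given acceleration voltage.
"CTF correction" here means phase flipping only (multiplying each Fourier
coefficient by the sign of the CTF at its radial frequency): it restores the
sign of the contrast without amplifying noise, and it is an involution,
which makes it directly testable.  Astigmatism is not modelled; each
particle carries a single defocus value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage


@dataclass(frozen=True)
class CTFParams:
    defocus_um: float          # underfocus positive
    voltage_kV: float = 120.0
    cs_mm: float = 2.0
    amplitude_contrast: float = 0.07
    pixel_A: float = 2.02

    def __post_init__(self):
        if not (0.0 < self.defocus_um <= 10.0):
            raise ValueError("defocus_um must be in (0, 10]")
        if not (0.0 <= self.amplitude_contrast <= 0.3):
            raise ValueError("amplitude_contrast must be in [0, 0.3]")


@dataclass(frozen=True)
class FilterSpec:
    """Band-pass specification in Angstrom wavelengths.

    Amplitudes at wavelengths longer than ``low_A`` are multiplied by
    ``low_freq_factor`` (0 removes them); wavelengths shorter than ``high_A``
    are rolled off to zero.  Edges are raised-cosine, two Fourier pixels wide.
    """

    low_A: float
    high_A: float
    low_freq_factor: float = 0.0

    def validate(self, pixel_A: float) -> None:
        if not (self.low_A > self.high_A):
            raise ValueError("low_A must exceed high_A")
        if self.high_A < 2.0 * pixel_A:
            raise ValueError(
                f"high_A={self.high_A} below Nyquist for pixel {pixel_A}")


def electron_wavelength_A(voltage_kV: float) -> float:
    """Relativistic de Broglie wavelength of electrons, in Angstroms."""
    V = voltage_kV * 1e3
    return 12.2639 / np.sqrt(V + 0.97845e-6 * V**2)


def ctf_evaluate(params: CTFParams, spatial_freq) -> np.ndarray:
    """CTF value at spatial frequency (1/A); bounded in [-1, 1]."""
    f = np.asarray(spatial_freq, dtype=float)
    if np.any(f < 0):
        raise ValueError("spatial frequency must be non-negative")
    lam = electron_wavelength_A(params.voltage_kV)
    dz = params.defocus_um * 1e4   # A
    cs = params.cs_mm * 1e7        # A
    chi = np.pi * lam * dz * f**2 - 0.5 * np.pi * cs * lam**3 * f**4
    A = params.amplitude_contrast
    return -(np.sqrt(1.0 - A**2) * np.sin(chi) + A * np.cos(chi))


def _radial_freq_grid(n: int, pixel_A: float) -> np.ndarray:
    fx = np.fft.fftfreq(n, d=pixel_A)
    return np.sqrt(fx[:, None] ** 2 + fx[None, :] ** 2)


def apply_ctf(image: np.ndarray, params: CTFParams) -> np.ndarray:
    """Multiply the image spectrum by the radially symmetric CTF."""
    freqs = _radial_freq_grid(image.shape[0], params.pixel_A)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * ctf_evaluate(params, freqs)))


def phase_flip(image: np.ndarray, params: CTFParams) -> np.ndarray:
    """Flip the sign of Fourier coefficients where the CTF is negative."""
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("phase_flip expects a square image")
    freqs = _radial_freq_grid(image.shape[0], params.pixel_A)
    sign = np.sign(ctf_evaluate(params, freqs))
    sign[sign == 0] = 1.0
    return np.real(np.fft.ifft2(np.fft.fft2(image) * sign))


def bin2x2(image: np.ndarray) -> np.ndarray:
    """Average 2x2 pixel blocks (doubles the pixel size)."""
    n0, n1 = image.shape
    if n0 % 2 or n1 % 2:
        raise ValueError("bin2x2 requires even dimensions")
    return image.reshape(n0 // 2, 2, n1 // 2, 2).mean(axis=(1, 3))


def extract_box(image: np.ndarray, center: tuple[int, int], box: int) -> np.ndarray:
    """Extract a box x box window centered on ``center`` = (cx, cy)."""
    cx, cy = center
    h = box // 2
    x0, y0 = cx - h, cy - h
    if x0 < 0 or y0 < 0 or x0 + box > image.shape[0] or y0 + box > image.shape[1]:
        raise ValueError("box extends beyond the image")
    return image[x0 : x0 + box, y0 : y0 + box].copy()


def crop_box(image: np.ndarray, box: int) -> np.ndarray:
    """Centered crop to box x box."""
    n0, n1 = image.shape
    if box > n0 or box > n1:
        raise ValueError("crop larger than the box")
    x0 = (n0 - box) // 2
    y0 = (n1 - box) // 2
    return image[x0 : x0 + box, y0 : y0 + box].copy()


def raised_cosine_gain(freqs: np.ndarray, spec: FilterSpec, df: float,
                       nyquist: float | None = None) -> np.ndarray:
    """Radial amplitude gain for a band-pass with soft (raised-cosine) edges.

    The low edge rises from ``low_freq_factor`` to 1 over two Fourier pixels
    ending at 1/low_A; the high edge falls from 1 to 0 over two Fourier
    pixels starting at 1/high_A.  If a cutoff lies at or beyond the Nyquist
    frequency the corresponding edge is a no-op, so low_freq_factor = 1 with
    high_A at Nyquist is the identity filter.
    """
    f_lo = 1.0 / spec.low_A
    f_hi = 1.0 / spec.high_A
    w = 2.0 * df
    gain = np.ones_like(freqs)

    if spec.low_freq_factor != 1.0:
        lo_start = max(f_lo - w, 0.0)
        t = np.clip((freqs - lo_start) / max(f_lo - lo_start, 1e-30), 0.0, 1.0)
        rise = 0.5 - 0.5 * np.cos(np.pi * t)
        gain *= spec.low_freq_factor + (1.0 - spec.low_freq_factor) * rise

    if nyquist is None or f_hi < nyquist:
        t = np.clip((freqs - f_hi) / w, 0.0, 1.0)
        gain *= 0.5 + 0.5 * np.cos(np.pi * t)
    return gain


def bandpass(image: np.ndarray, spec: FilterSpec, pixel_A: float) -> np.ndarray:
    """Soft-edged annular band-pass in the Fourier domain (linear filter)."""
    spec.validate(pixel_A)
    n = image.shape[0]
    freqs = _radial_freq_grid(n, pixel_A)
    gain = raised_cosine_gain(freqs, spec, df=1.0 / (n * pixel_A),
                              nyquist=0.5 / pixel_A)
    return np.real(np.fft.ifft2(np.fft.fft2(image) * gain))


def bandpass_normalize(
    image: np.ndarray,
    spec: FilterSpec,
    pixel_A: float,
    mask_radius_frac: float = 0.4,
) -> np.ndarray:
    """Band-pass, remove the mean (zero DC), scale background variance to 1.

    The normalization statistics are taken outside a circular particle mask
    of radius ``mask_radius_frac`` times the box width, so the particle
    itself does not bias the noise scaling.
    """
    from .phantom import circular_mask

    filt = bandpass(image, spec, pixel_A)
    filt = filt - filt.mean()
    outside = ~circular_mask(image.shape[0], mask_radius_frac * image.shape[0])
    bg = filt[outside]
    std = bg.std()
    if std == 0:
        return filt
    return filt / std


def rotate_image(image: np.ndarray, angle_deg: float, order: int = 1) -> np.ndarray:
    """Rotate about the image center (same grid, zero fill)."""
    return ndimage.rotate(image, angle_deg, reshape=False, order=order,
                          mode="constant", cval=0.0, prefilter=(order > 1))
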