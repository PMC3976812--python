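"""Heterogeneity index extraction.

72 named indices are computed from the eight parent matrices plus raw VOI
intensity statistics, in a canonical family order:

======  ==============================================  =====
prefix  family                                          count
======  ==============================================  =====
COOC    gray-level co-occurrence                            6
VA      voxel alignment (run length)                       11
NID     neighborhood intensity difference (NGTDM)           5
ISZ     intensity size zone                                11
NCOOC   normalized co-occurrence                            7
STAT    voxel statistics (SUV, TLG, volume, ...)           13
TS      texture spectrum                                    2
TFC     texture feature coding                              3
TFCC    TFC co-occurrence                                   9
NGLD    neighborhood gray-level dependence                  5
======  ==============================================  =====

All entropies are base 2 (bits). Degenerate sub-features (for example the
correlation of a constant VOI) return guarded finite values and append a
machine-readable warning instead of producing NaN.

User-defined indices can be added through :func:`register_feature`; they are
appended after the canonical 72 in every extraction.
"""

from __future__ import annotations

import dataclasses
import math
from functools import cached_property
from typing import Callable, Iterator, Mapping

import numpy as np

from .config import HetexConfig
from .parent_matrices import (CooccurrenceMatrix, NgldmMatrix, NgtdmVectors,
                              RunLengthMatrix, SizeZoneMatrix, TextureSpectrum,
                              TfcImage, cooccurrence, ngldm, ngtdm, size_zone,
                              texture_spectrum, texture_unit_complement, tfc,
                              tfc_cooccurrence, voxel_alignment)
from .quantization import QuantizedVoi, quantize_values, redigitize
from .volume_io import ImageVolume, VoiMask

__all__ = [
    "FeatureVector",
    "canonical_feature_names",
    "register_feature",
    "unregister_feature",
    "compute_all_features",
    "compute_feature",
    "FeatureContext",
    "cooccurrence_features",
    "normalized_cooccurrence_features",
    "run_length_features",
    "size_zone_features",
    "ngtdm_features",
    "ngldm_features",
    "texture_spectrum_features",
    "tfc_features",
    "tfc_cooccurrence_features",
    "voxel_statistics",
]

EPS = 1e-12


@dataclasses.dataclass
class FeatureVector(Mapping):
    """Ordered, named map of heterogeneity indices for one VOI."""

    values: dict[str, float]
    warnings: list[str] = dataclasses.field(default_factory=list)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


# ---------------------------------------------------------------------------
# Co-occurrence families
# ---------------------------------------------------------------------------

def cooccurrence_features(m: CooccurrenceMatrix) -> dict[str, float]:
    """Second angular moment, contrast, entropy, homogeneity, dissimilarity
    and inverse difference moment over the co-occurrence probabilities."""
    p = m.p
    v = m.level_values
    d = np.abs(v[:, None] - v[None, :])
    return {
        "second_angular_moment": float((p ** 2).sum()),
        "contrast": float((d ** 2 * p).sum()),
        "entropy": _entropy_bits(p.ravel()),
        "homogeneity": float((p / (1.0 + d)).sum()),
        "dissimilarity": float((d * p).sum()),
        "inverse_difference_moment": float((p / (1.0 + d ** 2)).sum()),
    }


def normalized_cooccurrence_features(m: CooccurrenceMatrix,
                                     warn: list[str] | None = None) -> dict[str, float]:
    """The six co-occurrence indices on standardized levels, plus correlation.

    Correlation is sum((i-mu)(j-mu) p) / sigma^2 with mu, sigma the marginal
    mean/SD; a zero-variance marginal is degenerate and yields 0 with a
    warning.
    """
    base = cooccurrence_features(m)
    p = m.p
    v = m.level_values
    if m.degenerate:
        corr = 0.0
        if warn is not None:
            warn.append("NCOOC_correlation: zero marginal variance, value set to 0")
    else:
        # level_values are already standardized, so correlation is E[z_i z_j]
        corr = float((v[:, None] * v[None, :] * p).sum())
    out = {k: base[k] for k in ("second_angular_moment", "contrast", "entropy",
                                "homogeneity", "inverse_difference_moment",
                                "dissimilarity")}
    out["correlation"] = corr
    return out


# ---------------------------------------------------------------------------
# Run length / size zone (shared functional forms)
# ---------------------------------------------------------------------------

def _emphasis_features(mat: np.ndarray, long_name: str, short_name: str,
                       scanned: int, percent_name: str,
                       length_variability_name: str) -> dict[str, float]:
    """Weighted-emphasis statistics shared by the run-length and size-zone
    families. ``mat[i-1, j-1]`` counts runs/zones of level i and length j."""
    n = mat.sum()
    i = np.arange(1, mat.shape[0] + 1, dtype=float)[:, None]
    j = np.arange(1, mat.shape[1] + 1, dtype=float)[None, :]
    w = mat / n
    return {
        short_name: float((w / j ** 2).sum()),
        long_name: float((w * j ** 2).sum()),
        "intensity_variability": float((mat.sum(axis=1) ** 2).sum() / n),
        length_variability_name: float((mat.sum(axis=0) ** 2).sum() / n),
        percent_name: float(n / scanned),
        "low_intensity": float((w / i ** 2).sum()),
        "high_intensity": float((w * i ** 2).sum()),
        "low_intensity_short": float((w / (i ** 2 * j ** 2)).sum()),
        "high_intensity_short": float((w * i ** 2 / j ** 2).sum()),
        "low_intensity_long": float((w * j ** 2 / i ** 2).sum()),
        "high_intensity_long": float((w * i ** 2 * j ** 2).sum()),
    }


def run_length_features(m: RunLengthMatrix) -> dict[str, float]:
    """Eleven run-emphasis statistics; run percentage is the run count over
    the number of voxels scanned (n_voxels x n_directions)."""
    f = _emphasis_features(m.r, "long_run_emphasis", "short_run_emphasis",
                           m.n_voxels * m.n_directions, "run_percentage",
                           "run_length_variability")
    return {
        "short_run_emphasis": f["short_run_emphasis"],
        "long_run_emphasis": f["long_run_emphasis"],
        "intensity_variability": f["intensity_variability"],
        "run_length_variability": f["run_length_variability"],
        "run_percentage": f["run_percentage"],
        "low_intensity_run_emphasis": f["low_intensity"],
        "high_intensity_run_emphasis": f["high_intensity"],
        "low_intensity_short_run_emphasis": f["low_intensity_short"],
        "high_intensity_short_run_emphasis": f["high_intensity_short"],
        "low_intensity_long_run_emphasis": f["low_intensity_long"],
        "high_intensity_long_run_emphasis": f["high_intensity_long"],
    }


def size_zone_features(m: SizeZoneMatrix) -> dict[str, float]:
    """Eleven zone-emphasis statistics, identical functional forms to the
    run-length family with zone sizes in place of run lengths."""
    f = _emphasis_features(m.z, "large_zone_emphasis", "short_zone_emphasis",
                           m.n_voxels, "zone_percentage", "size_zone_variability")
    return {
        "short_zone_emphasis": f["short_zone_emphasis"],
        "large_zone_emphasis": f["large_zone_emphasis"],
        "intensity_variability": f["intensity_variability"],
        "size_zone_variability": f["size_zone_variability"],
        "zone_percentage": f["zone_percentage"],
        "low_intensity_zone_emphasis": f["low_intensity"],
        "high_intensity_zone_emphasis": f["high_intensity"],
        "low_intensity_short_zone_emphasis": f["low_intensity_short"],
        "high_intensity_short_zone_emphasis": f["high_intensity_short"],
        "low_intensity_large_zone_emphasis": f["low_intensity_long"],
        "high_intensity_large_zone_emphasis": f["high_intensity_long"],
    }


# ---------------------------------------------------------------------------
# NGTDM
# ---------------------------------------------------------------------------

def ngtdm_features(v: NgtdmVectors) -> dict[str, float]:
    """Coarseness, contrast, busyness, complexity and strength from the
    neighborhood gray-tone difference vectors, with epsilon guards on the
    divisions (a perfectly homogeneous VOI hits the 1/EPS coarseness ceiling)."""
    occ = np.flatnonzero(v.p > 0)
    levels = (occ + 1).astype(float)
    p = v.p[occ]
    s = v.s[occ]
    n = v.n_total
    ng = len(occ)
    ps = float((p * s).sum())

    coarseness = 1.0 / (EPS + ps)
    if ng < 2:
        contrast = 0.0
        busyness = 0.0
    else:
        dif2 = (levels[:, None] - levels[None, :]) ** 2
        contrast = float((p[:, None] * p[None, :] * dif2).sum()
                         / (ng * (ng - 1)) * (s.sum() / n))
        denom = float(np.abs(levels[:, None] * p[:, None]
                             - levels[None, :] * p[None, :]).sum())
        busyness = ps / (denom + EPS)
    dif = np.abs(levels[:, None] - levels[None, :])
    psum = p[:, None] + p[None, :]
    complexity = float((dif / (n * psum) * (p[:, None] * s[:, None]
                                            + p[None, :] * s[None, :])).sum())
    strength = float((psum * dif ** 2).sum()) / (EPS + float(s.sum()))
    return {
        "coarseness": coarseness,
        "contrast": contrast,
        "busyness": busyness,
        "complexity": complexity,
        "strength": strength,
    }


# ---------------------------------------------------------------------------
# NGLDM
# ---------------------------------------------------------------------------

def ngldm_features(m: NgldmMatrix) -> dict[str, float]:
    """Small/large-number emphasis, number nonuniformity, second moment and
    entropy over the dependence-count matrix; dependence k is weighted by
    (k+1)^2 so an isolated voxel (k = 0) is well defined."""
    q = m.q.astype(float)
    total = q.sum()
    w = q / total
    k1 = (np.arange(q.shape[1], dtype=float) + 1.0)[None, :]
    return {
        "small_number_emphasis": float((w / k1 ** 2).sum()),
        "large_number_emphasis": float((w * k1 ** 2).sum()),
        "number_nonuniformity": float((q.sum(axis=0) ** 2).sum() / total),
        "second_moment": float((w ** 2).sum()),
        "entropy": _entropy_bits(w.ravel()),
    }


# ---------------------------------------------------------------------------
# Texture spectrum
# ---------------------------------------------------------------------------

def texture_spectrum_features(ts: TextureSpectrum) -> dict[str, float]:
    """Max spectrum (peak relative frequency) and black-white symmetry
    (1 minus the normalized absolute asymmetry under the digit complement
    that swaps darker/brighter comparisons)."""
    total = ts.s.sum()
    comp = texture_unit_complement()
    asym = float(np.abs(ts.s - ts.s[comp]).sum()) / (2.0 * total)
    return {
        "max_spectrum": float(ts.s.max() / total),
        "black_white_symmetry": 1.0 - asym,
    }


# ---------------------------------------------------------------------------
# Texture feature coding
# ---------------------------------------------------------------------------

def tfc_features(t: TfcImage, warn: list[str] | None = None) -> dict[str, float]:
    """Coarseness, homogeneity and mean convergence of the code image.

    Definitions (documented conventions of this package, structured after the
    texture-feature-coding scheme): coarseness is the fraction of coded
    voxels in the zero-variation class; homogeneity is the angular second
    moment of the code histogram; mean convergence is the mean absolute
    deviation of the codes in units of their SD (0 with a warning when the
    codes are constant).
    """
    values = t.values.astype(float)
    n = len(values)
    hist = np.bincount(values.astype(np.intp))
    p = hist / n
    mu = float(values.mean())
    sd = float(values.std())
    if sd > 0:
        mean_convergence = float(np.abs(values - mu).mean() / sd)
    else:
        mean_convergence = 0.0
        if warn is not None:
            warn.append("TFC_mean_convergence: constant codes, value set to 0")
    return {
        "coarseness": float((values == 0).mean()),
        "homogeneity": float((p ** 2).sum()),
        "mean_convergence": mean_convergence,
    }


def tfc_cooccurrence_features(m: CooccurrenceMatrix,
                              warn: list[str] | None = None) -> dict[str, float]:
    """Nine indices over the code co-occurrence matrix: the Haralick forms
    plus intensity (sum i*j*p), variance (sum (i-mu)^2 p_i) and code
    similarity (the diagonal mass: probability that a code pair agrees)."""
    base = cooccurrence_features(m)
    p = m.p
    v = m.level_values
    marg = p.sum(axis=1)
    mu = float(marg @ v)
    var = float(marg @ (v - mu) ** 2)
    if var > 0:
        corr = float(((v[:, None] - mu) * (v[None, :] - mu) * p).sum() / var)
    else:
        corr = 0.0
        if warn is not None:
            warn.append("TFCC_correlation: zero marginal variance, value set to 0")
    return {
        "second_angular_moment": base["second_angular_moment"],
        "contrast": base["contrast"],
        "entropy": base["entropy"],
        "homogeneity": base["homogeneity"],
        "intensity": float((v[:, None] * v[None, :] * p).sum()),
        "inverse_difference_moment": base["inverse_difference_moment"],
        "correlation": corr,
        "variance": var,
        "code_similarity": float(np.trace(p)),
    }


# ---------------------------------------------------------------------------
# Voxel statistics
# ---------------------------------------------------------------------------

def voxel_statistics(vol: ImageVolume, mask: VoiMask, levels: int = 64,
                     sul_scale: float = 1.0,
                     warn: list[str] | None = None) -> dict[str, float]:
    """First-order statistics of the raw VOI intensities.

    Moments use the population denominator n; the bias-corrected skewness
    and kurtosis apply the standard small-sample correction factors. Tumor
    volume is in mL, TLG = SUV_mean x volume. Entropy is the Shannon entropy
    (bits) of the redigitized L-level histogram. SUL_peak is the maximum
    over VOI voxels of the mean intensity inside a 1 mL sphere centered at
    the voxel (rasterized in index space from the voxel spacing), scaled by
    ``sul_scale`` (lean mass / body weight; defaults to 1 with a warning
    since a body-weight SUV is then reported in its place).
    """
    mask.check_aligned(vol)
    values = vol.voxels[mask.mask]
    n = len(values)
    if n < 2:
        raise ValueError("VOI must contain at least 2 voxels")
    if warn is not None and vol.intensity_units != "SUV":
        warn.append(f"STAT: intensities are {vol.intensity_units}, not SUV")
    mean = float(values.mean())
    centered = values - mean
    m2 = float((centered ** 2).mean())
    m3 = float((centered ** 3).mean())
    m4 = float((centered ** 4).mean())
    sd = math.sqrt(m2)
    if m2 > 0:
        skew = m3 / m2 ** 1.5
        kurt = m4 / m2 ** 2
    else:
        skew, kurt = 0.0, 0.0
        if warn is not None:
            warn.append("STAT: zero variance, skewness/kurtosis set to 0")
    if m2 > 0 and n > 2:
        skew_bc = skew * math.sqrt(n * (n - 1)) / (n - 2)
    else:
        skew_bc = 0.0
    if m2 > 0 and n > 3:
        kurt_bc = ((n + 1) * (kurt - 3.0) + 6.0) * (n - 1) / ((n - 2) * (n - 3)) + 3.0
    else:
        kurt_bc = 0.0

    volume_ml = n * vol.voxel_volume_ml
    lev, _, _ = quantize_values(values, levels)
    hist = np.bincount(lev, minlength=levels + 1)[1:]
    entropy = _entropy_bits(hist / n)

    if warn is not None and sul_scale == 1.0 and vol.intensity_units == "SUV":
        warn.append("STAT_sul_peak: no lean-mass scale supplied, using body weight")
    sul_peak = _peak_sphere_mean(vol, mask) * sul_scale

    return {
        "suv_min": float(values.min()),
        "suv_max": float(values.max()),
        "suv_mean": mean,
        "suv_variance": m2,
        "suv_sd": sd,
        "suv_skewness": skew,
        "suv_kurtosis": kurt,
        "suv_skewness_bias_corrected": skew_bc,
        "suv_kurtosis_bias_corrected": kurt_bc,
        "tlg": mean * volume_ml,
        "tumor_volume": volume_ml,
        "entropy": entropy,
        "sul_peak": sul_peak,
    }


def _sphere_offsets(spacing_mm, volume_ml: float = 1.0) -> np.ndarray:
    """Index offsets of voxels whose centers lie in a sphere of the given
    volume centered on a voxel center."""
    radius = (3.0 * volume_ml * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0)
    dz, dy, dx = spacing_mm
    nz, ny, nx = (int(radius // s) for s in (dz, dy, dx))
    zz, yy, xx = np.mgrid[-nz:nz + 1, -ny:ny + 1, -nx:nx + 1]
    inside = (zz * dz) ** 2 + (yy * dy) ** 2 + (xx * dx) ** 2 <= radius ** 2
    return np.stack([zz[inside], yy[inside], xx[inside]], axis=1)


def _peak_sphere_mean(vol: ImageVolume, mask: VoiMask) -> float:
    """Max over VOI voxels of the mean intensity in a 1 mL sphere."""
    offsets = _sphere_offsets(vol.spacing_mm)
    coords = np.argwhere(mask.mask)
    sums = np.zeros(len(coords))
    counts = np.zeros(len(coords))
    shape = np.asarray(vol.shape)
    for off in offsets:
        pos = coords + off
        ok = np.all((pos >= 0) & (pos < shape), axis=1)
        sums[ok] += vol.voxels[pos[ok, 0], pos[ok, 1], pos[ok, 2]]
        counts[ok] += 1
    return float((sums / counts).max())


# ---------------------------------------------------------------------------
# Registry and full extraction
# ---------------------------------------------------------------------------

class FeatureContext:
    """Lazily built parent matrices and family values for one VOI.

    Family results are cached, so registry entries of the same family share
    one matrix build. ``warnings`` collects degenerate-value notes.
    """

    def __init__(self, vol: ImageVolume, mask: VoiMask,
                 config: HetexConfig | None = None):
        self.vol = vol
        self.mask = mask
        self.config = config or HetexConfig()
        self.warnings: list[str] = []

    @cached_property
    def q(self) -> QuantizedVoi:
        return redigitize(self.vol, self.mask, self.config.levels)

    @cached_property
    def _tfc_image(self) -> TfcImage:
        return tfc(self.q, self.config.tfc_delta)

    @cached_property
    def families(self) -> dict[str, Callable[[], dict[str, float]]]:
        cfg = self.config
        return {
            "COOC": lambda: cooccurrence_features(
                cooccurrence(self.q, cfg.distance)),
            "VA": lambda: run_length_features(voxel_alignment(self.q)),
            "NID": lambda: ngtdm_features(ngtdm(self.q)),
            "ISZ": lambda: size_zone_features(
                size_zone(self.q, cfg.connectivity)),
            "NCOOC": lambda: normalized_cooccurrence_features(
                cooccurrence(self.q, cfg.distance, normalized=True),
                self.warnings),
            "STAT": lambda: voxel_statistics(
                self.vol, self.mask, cfg.levels, cfg.sul_scale, self.warnings),
            "TS": lambda: texture_spectrum_features(texture_spectrum(self.q)),
            "TFC": lambda: tfc_features(self._tfc_image, self.warnings),
            "TFCC": lambda: tfc_cooccurrence_features(
                tfc_cooccurrence(self._tfc_image, cfg.distance), self.warnings),
            "NGLD": lambda: ngldm_features(ngldm(self.q, cfg.ngldm_a)),
        }

    def family_values(self, family: str) -> dict[str, float]:
        cache = getattr(self, "_family_cache", None)
        if cache is None:
            cache = self._family_cache = {}
        if family not in cache:
            try:
                cache[family] = self.families[family]()
            except ValueError as exc:
                raise ValueError(f"{family}: {exc}") from exc
        return cache[family]

    def get(self, name: str) -> float:
        return FEATURE_REGISTRY[name](self)


_FAMILY_MEMBERS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("COOC", ("second_angular_moment", "contrast", "entropy", "homogeneity",
              "dissimilarity", "inverse_difference_moment")),
    ("VA", ("short_run_emphasis", "long_run_emphasis", "intensity_variability",
            "run_length_variability", "run_percentage",
            "low_intensity_run_emphasis", "high_intensity_run_emphasis",
            "low_intensity_short_run_emphasis", "high_intensity_short_run_emphasis",
            "low_intensity_long_run_emphasis", "high_intensity_long_run_emphasis")),
    ("NID", ("coarseness", "contrast", "busyness", "complexity", "strength")),
    ("ISZ", ("short_zone_emphasis", "large_zone_emphasis", "intensity_variability",
             "size_zone_variability", "zone_percentage",
             "low_intensity_zone_emphasis", "high_intensity_zone_emphasis",
             "low_intensity_short_zone_emphasis", "high_intensity_short_zone_emphasis",
             "low_intensity_large_zone_emphasis", "high_intensity_large_zone_emphasis")),
    ("NCOOC", ("second_angular_moment", "contrast", "entropy", "homogeneity",
               "inverse_difference_moment", "dissimilarity", "correlation")),
    ("STAT", ("suv_min", "suv_max", "suv_mean", "suv_variance", "suv_sd",
              "suv_skewness", "suv_kurtosis", "suv_skewness_bias_corrected",
              "suv_kurtosis_bias_corrected", "tlg", "tumor_volume", "entropy",
              "sul_peak")),
    ("TS", ("max_spectrum", "black_white_symmetry")),
    ("TFC", ("coarseness", "homogeneity", "mean_convergence")),
    ("TFCC", ("second_angular_moment", "contrast", "entropy", "homogeneity",
              "intensity", "inverse_difference_moment", "correlation",
              "variance", "code_similarity")),
    ("NGLD", ("small_number_emphasis", "large_number_emphasis",
              "number_nonuniformity", "second_moment", "entropy")),
)


def _make_entry(family: str, member: str) -> Callable[[FeatureContext], float]:
    def entry(ctx: FeatureContext) -> float:
        return ctx.family_values(family)[member]
    entry.family = family  # type: ignore[attr-defined]
    return entry


FEATURE_REGISTRY: dict[str, Callable[[FeatureContext], float]] = {
    f"{family}_{member}": _make_entry(family, member)
    for family, members in _FAMILY_MEMBERS for member in members
}
_CANONICAL_NAMES = tuple(FEATURE_REGISTRY)
assert len(_CANONICAL_NAMES) == 72


def canonical_feature_names() -> list[str]:
    """The 72 canonical feature names in extraction order."""
    return list(_CANONICAL_NAMES)


def family_of(name: str) -> str:
    return name.split("_", 1)[0]


def register_feature(name: str, func: Callable[[FeatureContext], float]) -> None:
    """Register a user-defined index; it is appended to every extraction."""
    if name in FEATURE_REGISTRY:
        raise ValueError(f"feature {name!r} already registered")
    FEATURE_REGISTRY[name] = func


def unregister_feature(name: str) -> None:
    if name in _CANONICAL_NAMES:
        raise ValueError("cannot remove a canonical feature")
    FEATURE_REGISTRY.pop(name, None)


def compute_all_features(vol: ImageVolume, mask: VoiMask,
                         config: HetexConfig | None = None) -> FeatureVector:
    """Run the full pipeline and return every registered index.

    The canonical 72 indices come first, in the fixed family order; any
    user-registered indices follow. Builder failures propagate with the
    family name attached; degenerate sub-features return guarded values and
    append to the warning list.
    """
    ctx = FeatureContext(vol, mask, config)
    values = {name: ctx.get(name) for name in FEATURE_REGISTRY}
    return FeatureVector(values, ctx.warnings)


def compute_feature(vol: ImageVolume, mask: VoiMask, name: str,
                    config: HetexConfig | None = None) -> float:
    """Compute a single registered index (used by parametric mapping)."""
    if name not in FEATURE_REGISTRY:
        raise KeyError(
            f"unknown feature {name!r}; known: {sorted(FEATURE_REGISTRY)}")
    return FeatureContext(vol, mask, config).get(name)
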