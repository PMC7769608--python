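"""Synthetic cohorts, line profiles and solver fixtures.

The generators emulate the statistical structure of the histology inputs so
that every analysis stage can be exercised without microscopy data:

* paranode-length cohorts — gamma-distributed lengths (strictly positive,
  right-skewed) with moments matched per group, a block (tissue-sample)
  hierarchy, and a block-level covariate (microglial area fraction) tied to
  the block mean length through a Gaussian copula with a target Spearman
  correlation;
* two-channel intensity profiles — plateau bands with error-function
  shoulders for the paranodal (Caspr1) and juxtaparanodal (Kv1.2) markers,
  where a dislocation parameter delta in [0, 1] slides the Kv band into the
  paranodal zone; additive Gaussian noise, clipped to the 8-bit range;
* a small multi-node axon fixture for fast solver tests.

Group defaults follow the study conditions: control paranodes 2.3 +/- 0.8
um, disease (MS-like) paranodes 2.8 +/- 1.1 um.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import erf

from .geometry import FibreClass, build_axon
from .profiles import INTENSITY_MAX, IntensityProfile

CONTROL_MEAN_UM = 2.3
CONTROL_SD_UM = 0.8
MS_MEAN_UM = 2.8
MS_SD_UM = 1.1


@dataclass(frozen=True)
class GroupSpec:
    """Target moments and sampling structure of one cohort group."""

    name: str
    mean_um: float
    sd_um: float
    n_paranodes: int
    n_blocks: int
    #: SD of the block-level shift of the mean, um
    block_sd_um: float = 0.15
    #: microglial area fraction covariate: mean and SD
    covariate_mean: float = 0.05
    covariate_sd: float = 0.02
    #: target Spearman correlation between block mean length and covariate
    rho_spearman: float = 0.45

    def __post_init__(self) -> None:
        if self.mean_um <= 0 or self.n_paranodes <= 0 or self.n_blocks <= 0:
            raise ValueError("means and sample sizes must be positive")
        if self.sd_um <= 0:
            raise ValueError("degenerate cohort: SD must be > 0 (gamma model)")
        if abs(self.rho_spearman) > 1:
            raise ValueError("|rho| must be <= 1")
        if self.block_sd_um >= self.sd_um:
            raise ValueError("block SD must be smaller than the total SD")


@dataclass(frozen=True)
class CohortSpec:
    groups: tuple[GroupSpec, ...]
    seed: int = 0


def default_cohort_spec(
    n_control: int = 3200,
    n_ms: int = 6800,
    blocks_control: int = 16,
    blocks_ms: int = 34,
    seed: int = 0,
) -> CohortSpec:
    """Cohort sized like the human study: control and MS-like groups."""
    return CohortSpec(
        groups=(
            GroupSpec("control", CONTROL_MEAN_UM, CONTROL_SD_UM, n_control, blocks_control),
            GroupSpec("MS", MS_MEAN_UM, MS_SD_UM, n_ms, blocks_ms),
        ),
        seed=seed,
    )


def _gamma_moment_match(mean: float, sd: float) -> tuple[float, float]:
    """Gamma (shape, scale) with the requested mean and SD."""
    shape = (mean / sd) ** 2
    scale = sd**2 / mean
    return shape, scale


def gen_length_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Generate a tidy cohort table (group, block, length_um, microglia_area).

    Within each group, block effects shift the gamma mean; the block
    covariate is coupled to the block effect by a Gaussian copula whose
    Pearson latent correlation 2 sin(pi rho_s / 6) hits the target Spearman
    rho. Fully reproducible from the seed carried by the cohort
    specification.
    """
    rng = np.random.default_rng(spec.seed)
    frames = []
    for g in spec.groups:
        z_block = rng.standard_normal(g.n_blocks)
        rho_p = 2.0 * math.sin(math.pi * g.rho_spearman / 6.0)
        eps = rng.standard_normal(g.n_blocks)
        u_block = rho_p * z_block + math.sqrt(1.0 - rho_p**2) * eps
        covariate = g.covariate_mean + g.covariate_sd * u_block

        # per-paranode sampling within blocks; within-block SD reduced so the
        # marginal SD matches the target
        within_sd = math.sqrt(max(g.sd_um**2 - g.block_sd_um**2, 1e-12))
        counts = np.full(g.n_blocks, g.n_paranodes // g.n_blocks)
        counts[: g.n_paranodes % g.n_blocks] += 1
        for b in range(g.n_blocks):
            mean_b = max(g.mean_um + g.block_sd_um * z_block[b], 0.2)
            shape, scale = _gamma_moment_match(mean_b, within_sd)
            lengths = rng.gamma(shape, scale, size=counts[b])
            lengths = np.maximum(lengths, 1e-3)
            frames.append(
                pd.DataFrame(
                    {
                        "group": g.name,
                        "block": f"{g.name}_{b:02d}",
                        "length_um": lengths,
                        "microglia_area": covariate[b],
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class ProfileSpec:
    """Geometry and noise of one synthetic two-channel line profile."""

    paranode_length_um: float = 2.3
    #: gap between the end of the paranode band and the start of the Kv band
    jxp_offset_um: float = 1.0
    jxp_length_um: float = 5.0
    #: fraction of the Kv band shifted into the paranodal zone
    delta: float = 0.0
    peak_intensity: float = 200.0
    noise_sd: float = 0.0
    step_um: float = 0.05
    shoulder_um: float = 0.15
    margin_um: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.delta <= 1.0:
            raise ValueError("delta must lie in [0, 1]")
        if self.noise_sd < 0 or self.step_um <= 0:
            raise ValueError("noise SD must be >= 0 and step > 0")


def _band(x: np.ndarray, lo: float, hi: float, amp: float, s: float) -> np.ndarray:
    """Plateau of height amp on [lo, hi] with erf shoulders of width s."""
    return amp * 0.5 * (erf((x - lo) / (s * math.sqrt(2))) - erf((x - hi) / (s * math.sqrt(2))))


def gen_profile(spec: ProfileSpec, axon_id: str = "axon") -> IntensityProfile:
    """Generate one aligned two-channel profile.

    The R band covers the paranode [0, L].  At delta = 0 the G band starts
    one offset beyond the paranode end; at delta = 1 its centre has moved
    into the middle of the paranodal zone.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.paranode_length_um
    g_lo0 = L + spec.jxp_offset_um
    shift = spec.delta * (spec.jxp_offset_um + L / 2.0 + spec.jxp_length_um / 2.0)
    g_lo = g_lo0 - shift
    g_hi = g_lo + spec.jxp_length_um

    x_max = g_lo0 + spec.jxp_length_um + spec.margin_um
    x = np.arange(-spec.margin_um, x_max + spec.step_um / 2, spec.step_um)
    red = _band(x, 0.0, L, spec.peak_intensity, spec.shoulder_um)
    green = _band(x, g_lo, g_hi, spec.peak_intensity, spec.shoulder_um)
    if spec.noise_sd > 0:
        red = red + rng.normal(0.0, spec.noise_sd, size=x.shape)
        green = green + rng.normal(0.0, spec.noise_sd, size=x.shape)
    red = np.clip(red, 0.0, INTENSITY_MAX)
    green = np.clip(green, 0.0, INTENSITY_MAX)
    return IntensityProfile(axon_id, x, red, green)


def gen_profile_cohort(
    n_axons: int,
    dislocated_fraction: float,
    delta_dislocated: float = 1.0,
    noise_sd: float = 5.0,
    seed: int = 0,
) -> list[IntensityProfile]:
    """A cohort where a known fraction of axons carries a dislocated Kv band."""
    if not 0.0 <= dislocated_fraction <= 1.0:
        raise ValueError("dislocated_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_disl = int(round(n_axons * dislocated_fraction))
    profiles = []
    for i in range(n_axons):
        delta = delta_dislocated if i < n_disl else 0.0
        profiles.append(
            gen_profile(
                ProfileSpec(
                    delta=delta,
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                ),
                axon_id=f"axon{i:04d}",
            )
        )
    return profiles


@dataclass(frozen=True)
class DisruptionFixture:
    """Small deterministic axon bundle for fast solver tests."""

    fibre_class: FibreClass
    n_nodes: int
    baseline_geometry: object
    disrupted_widths: tuple[float, float]


def gen_disruption_fixture(seed: int = 0, n_nodes: int = 7) -> DisruptionFixture:
    """A 7-node small-calibre axon and its 10x disrupted widths.

    Deterministic: the seed is accepted for interface uniformity but the
    fixture itself has no random content.
    """
    fc = FibreClass.from_diameters(0.8, 0.6)
    geom = build_axon(fc, n_nodes=n_nodes)
    return DisruptionFixture(
        fibre_class=fc,
        n_nodes=n_nodes,
        baseline_geometry=geom,
        disrupted_widths=(0.022, 0.22),
    )
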