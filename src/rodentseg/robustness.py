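"""Gaussian-noise robustness protocol.

Trained models are challenged with Gaussian white noise of SD sigma in
1..15 (step 1), added after min-max normalization of each modality to
the 0-255 range. The noised images are re-segmented by the cascade and
scored against the unchanged ground truth, while the signal-to-noise
ratio is measured on T2WI as

    SNR = mean(T2 over contralateral brain tissue) / SD(T2 over background),

with tissue = brain - tumor and background = air voxels eroded away from
the skull. Noised images are NOT re-clipped to [0, 255] by default:
clipping would bias the background SD and break the additive-variance
relationship SD_after = sqrt(SD_before^2 + sigma^2) (a ``clip`` flag
exists for pipelines that need bounded intensities).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .metrics import evaluate_pair
from .phantom import snr_regions_from_case
from .preprocess import normalize_intensity
from .segnet import UNet3D, segment_stepwise
from .volio import CaseRecord, Mask, ModalityStack, Volume, _check_lattice

DEFAULT_SIGMAS = tuple(range(1, 16))


@dataclass
class SnrRegions:
    """Tissue/background region pair for SNR measurement."""

    tissue: Mask
    background: Mask

    def __post_init__(self) -> None:
        _check_lattice(self.tissue.shape, self.tissue.spacing,
                       self.background.shape, self.background.spacing,
                       "SNR regions")
        if self.tissue.is_empty() or self.background.is_empty():
            raise ValueError("SNR regions must both be nonempty")
        if np.logical_and(self.tissue.as_bool(), self.background.as_bool()).any():
            raise ValueError("SNR regions must be disjoint")


def add_gaussian_noise(v: Volume, sigma: float, seed: int,
                       clip: bool = False) -> Volume:
    """Min-max normalize to [0, 255], then add i.i.d. N(0, sigma^2) noise.

    Deterministic given ``seed``; sigma=0 returns the normalized volume
    unchanged. Output is not clipped unless ``clip`` is set.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    out = normalize_intensity(v, "minmax255")
    if sigma == 0:
        return out
    rng = np.random.default_rng(seed)
    data = out.data + rng.normal(0.0, sigma, size=out.data.shape).astype(np.float32)
    if clip:
        data = np.clip(data, 0.0, 255.0)
    return out.with_data(data)


def compute_snr(v: Volume, regions: SnrRegions) -> float:
    """Tissue-mean over background-SD; NaN (warned) for zero background SD."""
    _check_lattice(v.shape, v.spacing, regions.tissue.shape,
                   regions.tissue.spacing, "SNR volume/regions")
    tissue_mean = float(v.data[regions.tissue.as_bool()].mean())
    bg_sd = float(v.data[regions.background.as_bool()].std())
    if bg_sd == 0.0:
        import logging
        logging.getLogger("rodentseg").warning(
            "SNR undefined: zero background SD")
        return float("nan")
    return tissue_mean / bg_sd


def _noise_seed(base_seed: int, case_idx: int, sigma_idx: int,
                modality_idx: int) -> int:
    """Independent, reproducible noise stream per (case, sigma, modality)."""
    ss = np.random.SeedSequence([int(base_seed), case_idx, sigma_idx,
                                 modality_idx])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def noised_stack(stack: ModalityStack, sigma: float, base_seed: int,
                 case_idx: int = 0, sigma_idx: int = 0,
                 clip: bool = False) -> ModalityStack:
    """Noise every modality independently (one seed stream per modality)."""
    vols = [add_gaussian_noise(v, sigma,
                               _noise_seed(base_seed, case_idx, sigma_idx, m),
                               clip=clip)
            for m, v in enumerate(stack.volumes)]
    return ModalityStack(*vols)


def run_noise_challenge(net1: UNet3D, net2: UNet3D, cases: list[CaseRecord],
                        sigmas=DEFAULT_SIGMAS, seeds=(0,),
                        threshold: float = 0.5) -> pd.DataFrame:
    """Metric-vs-SNR sweep for the trained cascade.

    For each case x sigma x seed: noise all modalities, re-run
    segment_stepwise, score both stages against the clean ground truth,
    and record the SNR measured on the noised T2WI over regions derived
    from the clean case. Returns a tidy frame with one row per case,
    stage, sigma and seed (row count = |cases| x |sigmas| x |seeds| x 2).
    """
    rows = []
    for ci, case in enumerate(cases):
        if case.brain_mask is None or case.tumor_mask is None:
            raise ValueError(f"case {case.case_id} lacks ground-truth masks")
        tissue, background = snr_regions_from_case(case)
        regions = SnrRegions(tissue=tissue, background=background)
        for seed in seeds:
            for si, sigma in enumerate(sigmas):
                stack = noised_stack(case.stack, sigma, seed, ci, si)
                snr = compute_snr(stack.t2, regions)
                brain, tumor = segment_stepwise(net1, net2, stack,
                                                threshold=threshold)
                for stage, pred, truth in (("brain", brain, case.brain_mask),
                                           ("tumor", tumor, case.tumor_mask)):
                    rep = evaluate_pair(pred, truth)
                    rows.append({"case_id": case.case_id, "stage": stage,
                                 "sigma": sigma, "seed": seed, "snr": snr,
                                 **{k: rep.as_dict()[k]
                                    for k in ("dsc", "rv", "msd", "hd")}})
    return pd.DataFrame(rows)
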