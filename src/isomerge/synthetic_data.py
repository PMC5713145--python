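"""Synthetic multi-crystal wedge generator with controllable isomorphism.

Emulates a serial-crystallography experiment in which many crystals each
contribute a small rotation wedge: a ground-truth intensity set is drawn
over the full asymmetric unit, organised into isomorphism classes with a
chosen between-class correlation, and each wedge samples a contiguous block
of unique reflections (plus random scatter) with per-observation noise,
per-dataset scale and per-class unit-cell jitter.

Wedges are index-block samples rather than geometric rotation simulations:
the clustering pipeline consumes only the intensity-overlap structure, so
full diffraction geometry is unnecessary at this scale.  Latent intensities
are log-normal, giving positivity and a heavy tail loosely mimicking Wilson
statistics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .reflection_io import PartialDataset, write_dataset
from .symmetry import (
    CrystalCell,
    SpaceGroupInfo,
    decode_keys,
    unique_reflections,
)

__all__ = ["SimulationConfig", "GroundTruth", "generate_ground_truth",
           "generate_partial_datasets", "simulate", "write_simulation"]

#: spread of the log-intensity distribution (log-normal shape parameter)
_LOG_SIGMA = 1.0
#: mean scale of true intensities, arbitrary units
_MEAN_INTENSITY = 1000.0


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic multi-crystal experiment.

    Defaults emulate a serial experiment on a tetragonal protein crystal
    form: 184 wedges at ~4.9% completeness each, a dominant isomorphism
    class plus a minority class, strong within-class correlation (0.95) and
    weak between-class correlation (0.30), 5% relative noise and a small
    per-class cell perturbation.
    """

    cell: CrystalCell = field(default_factory=lambda: CrystalCell(58.07, 58.07, 150.56))
    sg_number: int = 92
    d_min: float = 1.8
    n_classes: int = 2
    datasets_per_class: tuple[int, ...] = (138, 46)
    within_cc: float = 0.95
    between_cc: float = 0.30
    wedge_fraction: float = 0.049
    noise_level: float = 0.05
    cell_jitter: float = 0.002
    anomalous_signal: float = 0.0
    wavelength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.between_cc <= self.within_cc <= 1.0:
            raise ValueError("require 0 <= between_cc <= within_cc <= 1")
        if not 0.0 < self.wedge_fraction <= 1.0:
            raise ValueError("wedge_fraction must lie in (0, 1]")
        if len(self.datasets_per_class) != self.n_classes:
            raise ValueError("datasets_per_class must have n_classes entries")

    @property
    def spacegroup(self) -> SpaceGroupInfo:
        return SpaceGroupInfo.from_number(self.sg_number)


@dataclass
class GroundTruth:
    """True per-class intensities over the full unique set."""

    codes: np.ndarray          # encoded ASU keys, sorted
    hkl: np.ndarray            # (n, 3) representatives
    class_intensity: np.ndarray  # (n_classes, n) strictly positive
    config: SimulationConfig


def _mixing_weight(target_cc: float) -> float:
    """Latent mixing weight giving a target Pearson cc between log-normals.

    If two standard-normal latents have correlation w, the correlation of
    exp(s*z) variables is (exp(s^2 w) - 1) / (exp(s^2) - 1); invert for w.
    """
    s2 = _LOG_SIGMA**2
    if target_cc >= 1.0:
        return 1.0
    return math.log1p(target_cc * math.expm1(s2)) / s2


def generate_ground_truth(config: SimulationConfig) -> GroundTruth:
    """Draw per-class true intensity sets over all unique reflections.

    Class log-intensities share a latent component weighted so the expected
    Pearson correlation between any two class intensity sets equals
    ``between_cc``.
    """
    rng = np.random.default_rng(config.seed)
    codes, _ = unique_reflections(config.cell, config.spacegroup, config.d_min)
    hkl, _ = decode_keys(codes)
    n = len(codes)
    w = _mixing_weight(config.between_cc)
    shared = rng.standard_normal(n)
    mu = math.log(_MEAN_INTENSITY) - 0.5 * _LOG_SIGMA**2
    classes = []
    for _c in range(config.n_classes):
        own = rng.standard_normal(n)
        z = math.sqrt(w) * shared + math.sqrt(1.0 - w) * own
        classes.append(np.exp(mu + _LOG_SIGMA * z))
    return GroundTruth(
        codes=codes, hkl=hkl, class_intensity=np.stack(classes), config=config
    )


def _perturbation_scale(within_cc: float) -> float:
    """Relative multiplicative jitter giving a target within-class dataset cc.

    With I_d = I_c (1 + eta), eta ~ N(0, tau) iid, the correlation between
    two datasets of one class is Var(I_c) / (Var(I_c) + tau^2 E[I_c^2]);
    solved for tau using the log-normal moments.
    """
    if within_cc >= 1.0:
        return 0.0
    s2 = _LOG_SIGMA**2
    var_over_m2 = math.expm1(s2) * math.exp(-s2)  # Var(I)/E[I^2] for the latent
    return math.sqrt(var_over_m2 * (1.0 - within_cc) / within_cc)


def _jittered_cell(cell: CrystalCell, rel: np.ndarray) -> CrystalCell:
    return CrystalCell(
        cell.a * (1 + rel[0]),
        cell.b * (1 + rel[1]),
        cell.c * (1 + rel[2]),
        cell.alpha,
        cell.beta,
        cell.gamma,
    )


def generate_partial_datasets(
    config: SimulationConfig, truth: GroundTruth
) -> tuple[list[PartialDataset], list[int]]:
    """Sample wedge-style partial datasets from the ground truth.

    Each wedge covers a contiguous block of the sorted unique-reflection
    list plus a random scatter (70/30 split of the expected coverage
    ``wedge_fraction``), mimicking how a small rotation range samples
    reciprocal space unevenly.  Returns the datasets and their class labels.
    """
    rng = np.random.default_rng(config.seed + 1)
    n = len(truth.codes)
    tau = _perturbation_scale(config.within_cc)
    sg = config.spacegroup
    # one jittered cell per class, shared by its members
    class_cells = []
    for c in range(config.n_classes):
        rel = rng.normal(0.0, config.cell_jitter, size=3) if config.cell_jitter > 0 else np.zeros(3)
        class_cells.append(_jittered_cell(config.cell, rel))
    # per-key Bijvoet asymmetry shared within a class
    if config.anomalous_signal > 0:
        dano = rng.normal(0.0, config.anomalous_signal, size=(config.n_classes, n))
    else:
        dano = None

    datasets: list[PartialDataset] = []
    labels: list[int] = []
    idx = 0
    block_frac = 0.7
    for c, count in enumerate(config.datasets_per_class):
        for _ in range(count):
            block = max(1, int(round(block_frac * config.wedge_fraction * n)))
            start = rng.integers(0, n)
            chosen = (start + np.arange(block)) % n
            # scatter rate conditioned on the block so E[coverage] = wedge_fraction
            scatter_p = (config.wedge_fraction - block / n) / max(1e-12, 1.0 - block / n)
            scatter = np.flatnonzero(rng.random(n) < max(0.0, scatter_p))
            sel = np.unique(np.concatenate([chosen, scatter]))
            true_i = truth.class_intensity[c, sel]
            pert = rng.normal(0.0, tau, size=len(sel)) if tau > 0 else np.zeros(len(sel))
            signal = true_i * (1.0 + pert)
            hkl_sel = truth.hkl[sel]
            if dano is not None:
                half = 0.5 * dano[c, sel] * signal
            else:
                half = np.zeros(len(sel))
            # both Friedel mates of every sampled unique reflection
            values = np.concatenate([signal + half, signal - half])
            hkl_obs = np.concatenate([hkl_sel, -hkl_sel])
            sigma = config.noise_level * np.abs(values)
            sigma[sigma <= 0] = 1e-6 * _MEAN_INTENSITY
            if config.noise_level > 0:
                values = values + rng.normal(size=len(values)) * sigma
            datasets.append(
                PartialDataset(
                    id=f"wedge_{idx:04d}",
                    cell=class_cells[c],
                    spacegroup=sg,
                    hkl=hkl_obs,
                    intensity=values,
                    sigma=sigma,
                    wavelength=config.wavelength,
                )
            )
            labels.append(c)
            idx += 1
    return datasets, labels


def simulate(config: SimulationConfig) -> tuple[list[PartialDataset], list[int], GroundTruth]:
    """Generate truth and wedges in one call."""
    truth = generate_ground_truth(config)
    datasets, labels = generate_partial_datasets(config, truth)
    return datasets, labels, truth


def write_simulation(
    config: SimulationConfig, outdir: str | Path
) -> tuple[Path, Path]:
    """Write wedge files, a manifest and a ground-truth class-label JSON.

    Returns the manifest and ground-truth paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    datasets, labels, _ = simulate(config)
    manifest_path = outdir / "manifest.txt"
    with open(manifest_path, "w") as mfh:
        for ds in datasets:
            fname = f"{ds.id}.refl"
            write_dataset(ds, outdir / fname)
            mfh.write(f"{ds.id} {fname}\n")
    truth_path = outdir / "ground_truth.json"
    cfg = asdict(config)
    cfg["cell"] = list(config.cell.parameters())
    with open(truth_path, "w") as fh:
        json.dump(
            {
                "config": cfg,
                "classes": {ds.id: int(c) for ds, c in zip(datasets, labels)},
            },
            fh,
            indent=1,
        )
    return manifest_path, truth_path
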