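"""Synthetic data emulating the pipeline's study conditions.

Three generators, all pure functions of their configuration and an
rng seed:

* ``simulate_proteomehd`` -- a protein x perturbation log-ratio matrix
  with planted co-regulated modules.  Each module rides a shared latent
  perturbation response; member rows are the latent plus member noise,
  so the implied within-module pairwise correlation is
  response_sd^2 / (response_sd^2 + noise_sd^2).  Missingness is
  block-structured: each protein is observed in a random contiguous
  "project" window of experiments, mimicking per-project quantification.
* ``simulate_paired_omics`` -- matched mRNA/protein panels in which group
  coordination (shared latents) and mRNA-to-protein contribution (the
  coupling coefficient alpha) can be dialled independently.
* ``simulate_screen`` -- plate-structured siRNA screens with negative
  controls, plate offsets, per-siRNA efficacy variation and implanted
  true-positive genes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import RatioMatrix
from .downstream_stats import PairedOmics
from .screen_scoring import (
    DEFAULT_CONDITIONS,
    DEFAULT_READOUT_CATALOG,
    ScreenDataset,
)


@dataclass
class ModuleSpec:
    """A planted co-regulation module.

    ``response_sd`` scales the shared latent perturbation response and
    ``noise_sd`` the member-specific noise, so the implied pairwise
    correlation is response_sd^2 / (response_sd^2 + noise_sd^2);
    ``detection_fraction`` is the expected non-missing rate per member.
    """

    size: int
    response_sd: float = 1.0
    noise_sd: float = 0.5
    detection_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.size < 4:
            raise ValueError("module size must be >= 4")
        if not 0 < self.detection_fraction <= 1:
            raise ValueError("detection_fraction must be in (0, 1]")

    @property
    def target_pairwise_rho(self) -> float:
        v = self.response_sd ** 2
        return v / (v + self.noise_sd ** 2)

    @classmethod
    def from_rho(cls, size: int, rho: float,
                 detection_fraction: float = 1.0) -> "ModuleSpec":
        """Module with a target within-module correlation ``rho``."""
        if not 0 < rho < 1:
            raise ValueError("rho must be in (0, 1)")
        noise_sd = float(np.sqrt((1 - rho) / rho))
        return cls(size=size, response_sd=1.0, noise_sd=noise_sd,
                   detection_fraction=detection_fraction)


@dataclass
class SimulationTruth:
    """Ground truth of a simulation run, for tests and diagnostics."""

    module_members: dict[str, frozenset[str]] = field(default_factory=dict)
    latents: dict[str, np.ndarray] = field(default_factory=dict)
    coupling: dict[str, float] = field(default_factory=dict)
    true_positive_genes: frozenset[str] = frozenset()
    rng_seed: int = 0


def _block_missing_mask(n_prot: int, n_exp: int, detection: np.ndarray,
                        rng: np.random.Generator, block: bool = True) -> np.ndarray:
    """Observed-mask with per-protein contiguous observation windows."""
    mask = np.ones((n_prot, n_exp), dtype=bool)
    for i in range(n_prot):
        frac = detection[i]
        if frac >= 1.0:
            continue
        width = max(1, int(round(frac * n_exp)))
        if block:
            start = rng.integers(0, n_exp - width + 1)
            mask[i] = False
            mask[i, start:start + width] = True
        else:
            mask[i] = False
            mask[i, rng.choice(n_exp, size=width, replace=False)] = True
    return mask


def simulate_proteomehd(
    n_proteins: int = 500,
    n_experiments: int = 100,
    modules: list[ModuleSpec] | None = None,
    background_sd: float = 1.0,
    background_detection: float = 1.0,
    block_missingness: bool = True,
    heavy_tails: bool = False,
    rng_seed: int = 0,
) -> tuple[RatioMatrix, SimulationTruth]:
    """Ratio matrix with planted modules over independent background.

    Module member row = shared latent response + member noise;
    background rows are independent noise of scale ``background_sd``.
    With ``heavy_tails`` the noise is t-distributed (df=3, scaled to
    unit variance) to mimic ratio outliers.
    """
    modules = modules or []
    total = sum(ms.size for ms in modules)
    if total > n_proteins:
        raise ValueError(
            f"module sizes sum to {total} > n_proteins={n_proteins}")
    rng = np.random.default_rng(rng_seed)

    def noise(size, sd):
        if heavy_tails:
            return rng.standard_t(df=3, size=size) * sd / np.sqrt(3.0)
        return rng.normal(0.0, sd, size=size)

    values = np.empty((n_proteins, n_experiments))
    detection = np.full(n_proteins, background_detection)
    truth = SimulationTruth(rng_seed=rng_seed)
    ids: list[str] = []
    row = 0
    for k, ms in enumerate(modules):
        name = f"module_{k + 1}"
        z = rng.normal(0.0, ms.response_sd, size=n_experiments)
        members = []
        for _ in range(ms.size):
            values[row] = z + noise(n_experiments, ms.noise_sd)
            detection[row] = ms.detection_fraction
            members.append(f"M{k + 1}_P{row:05d}")
            ids.append(members[-1])
            row += 1
        truth.module_members[name] = frozenset(members)
        truth.latents[name] = z
    n_bg = n_proteins - row
    values[row:] = noise((n_bg, n_experiments), background_sd)
    ids.extend(f"BG_P{row + i:05d}" for i in range(n_bg))
    mask = _block_missing_mask(n_proteins, n_experiments, detection, rng,
                               block=block_missingness)
    values = np.where(mask, values, np.nan)
    df = pd.DataFrame(values, index=pd.Index(ids, name="protein_id"),
                      columns=[f"exp_{j + 1:03d}" for j in range(n_experiments)])
    return RatioMatrix(df), truth


@dataclass
class OmicsGroupSpec:
    """A gene group in a paired mRNA/protein panel.

    ``mrna_latent_sd`` controls mRNA coordination, ``coupling`` (alpha)
    the transmission of mRNA changes into protein changes, and
    ``protein_latent_sd`` a protein-level shared response that lets
    protein coordination exceed what mRNA transmits.
    """

    size: int
    mrna_latent_sd: float = 1.0
    coupling: float = 0.8
    protein_latent_sd: float = 0.0
    mrna_noise_sd: float = 0.5
    protein_noise_sd: float = 0.5


def simulate_paired_omics(
    n_genes: int = 200,
    n_samples: int = 36,
    groups: dict[str, OmicsGroupSpec] | None = None,
    rng_seed: int = 0,
) -> tuple[PairedOmics, SimulationTruth]:
    """Matched mRNA/protein matrices with controllable coupling.

    mrna(g) = group latent + noise; protein(g) = alpha * mrna(g) +
    protein-level group latent + noise.  Genes beyond the groups are
    independent background with coupling 0.
    """
    groups = groups or {}
    total = sum(g.size for g in groups.values())
    if total > n_genes:
        raise ValueError("group sizes exceed n_genes")
    rng = np.random.default_rng(rng_seed)
    mrna = np.empty((n_genes, n_samples))
    prot = np.empty((n_genes, n_samples))
    ids: list[str] = []
    truth = SimulationTruth(rng_seed=rng_seed)
    row = 0
    for name, spec in groups.items():
        zm = rng.normal(0.0, spec.mrna_latent_sd, size=n_samples)
        zp = rng.normal(0.0, spec.protein_latent_sd, size=n_samples) \
            if spec.protein_latent_sd > 0 else np.zeros(n_samples)
        members = []
        for _ in range(spec.size):
            gid = f"{name}_G{row:04d}"
            mrna[row] = zm + rng.normal(0.0, spec.mrna_noise_sd, size=n_samples)
            prot[row] = (spec.coupling * mrna[row] + zp
                         + rng.normal(0.0, spec.protein_noise_sd, size=n_samples))
            members.append(gid)
            ids.append(gid)
            row += 1
        truth.module_members[name] = frozenset(members)
        truth.coupling[name] = spec.coupling
    for i in range(n_genes - row):
        gid = f"BG_G{row + i:04d}"
        ids.append(gid)
        mrna[row + i] = rng.normal(0.0, 1.0, size=n_samples)
        prot[row + i] = rng.normal(0.0, 1.0, size=n_samples)
    cols = [f"sample_{j + 1:02d}" for j in range(n_samples)]
    idx = pd.Index(ids, name="gene_id")
    po = PairedOmics(
        mrna=pd.DataFrame(mrna, index=idx, columns=cols),
        protein=pd.DataFrame(prot, index=idx, columns=cols),
    )
    return po, truth


def simulate_screen(
    genes: list[str] | None = None,
    true_positives: list[str] | None = None,
    effect_size: float = 3.0,
    n_controls_per_plate: int = 8,
    control_sd: float = 0.1,
    plate_offset_sd: float = 0.2,
    sirna_efficacy_sd: float = 0.15,
    n_replicates: int = 3,
    n_replicates_aph: int = 6,
    rng_seed: int = 0,
) -> tuple[ScreenDataset, SimulationTruth]:
    """Plate-structured siRNA screen with implanted true positives.

    Control wells ~ N(plate offset, control_sd); true-positive genes are
    shifted by ``effect_size`` (in units of control_sd) in every
    readout, with per-siRNA efficacy variation.  Readouts containing
    "Aph" use ``n_replicates_aph`` replicates, the rest
    ``n_replicates``.
    """
    genes = genes if genes is not None else [f"GENE{i:03d}" for i in range(12)]
    tp = set(true_positives or [])
    rng = np.random.default_rng(rng_seed)
    readout_rows = []
    for readout in DEFAULT_READOUT_CATALOG:
        if DEFAULT_READOUT_CATALOG[readout] == "cell_cycle":
            for cond in DEFAULT_CONDITIONS:
                readout_rows.append((readout, cond))
        else:
            readout_rows.append((readout, ""))
    efficacy = {
        (g, s): max(0.2, 1.0 + rng.normal(0.0, sirna_efficacy_sd))
        for g, s in itertools.product(genes, range(1, 4))
    }
    rows = []
    for readout, cond in readout_rows:
        n_rep = n_replicates_aph if "Aph" in readout or "Aph" in cond else n_replicates
        for rep in range(1, n_rep + 1):
            plate = f"{readout}_{cond or 'na'}_rep{rep}"
            offset = rng.normal(0.0, plate_offset_sd)
            for c in range(n_controls_per_plate):
                rows.append((plate, f"ctrl_{c:02d}", "neg_ctrl", "NEG", readout,
                             cond, rep, offset + rng.normal(0.0, control_sd), True))
            w = 0
            for g in genes:
                shift = effect_size * control_sd if g in tp else 0.0
                for s in range(1, 4):
                    val = offset + shift * efficacy[(g, s)] \
                        + rng.normal(0.0, control_sd)
                    rows.append((plate, f"w_{w:03d}", f"{g}_si{s}", g, readout,
                                 cond, rep, val, False))
                    w += 1
    wells = pd.DataFrame(rows, columns=ScreenDataset.REQUIRED)
    truth = SimulationTruth(true_positive_genes=frozenset(tp), rng_seed=rng_seed)
    return ScreenDataset(wells=wells), truth
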