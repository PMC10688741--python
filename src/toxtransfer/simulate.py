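"""Synthetic multi-domain exposure datasets with known ground truth.

The generator emulates a liver toxicogenomics exposure design: 45 compounds at
four dose levels measured in rat hepatocytes in vitro (2, 8, 24 h; 2
replicates), human hepatocytes in vitro (same grid; 2 replicates) and rat
liver in vivo (3, 6, 9, 24 h; 3 replicates).

Each compound-gene response follows a gamma-shaped impulse: expression departs
from a gene-specific baseline, peaks at a compound-gene-specific time and
decays. Dose scales the response amplitude (control carries zero response).
The rat in vivo trajectory is a fixed smooth transform of the same latent
response (onset delay plus gene-specific gain) evaluated on the in vivo grid.
The human in vitro data are the rat in vitro latent response passed through a
systematic gene-wise affine domain shift (offset + gain) whose size is
controlled by ``domain_shift_magnitude``. Replicates differ only by i.i.d.
Gaussian noise truncated to [0, 1]. Because the noise-free trajectories are
fully determined by the stored :class:`GroundTruth`, every downstream stage
can be tested against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data_model import (
    DOSES,
    HUMAN_VITRO,
    RAT_VITRO,
    RAT_VIVO,
    VITRO_TIMES,
    VIVO_TIMES,
    ExposureDataset,
    ExposureSeries,
    GeneSet,
)
from .errors import NoLabelledCompoundsError

#: Relative response amplitude per dose level; control has no compound response.
DOSE_WEIGHTS = {"control": 0.0, "low": 1.0 / 3.0, "medium": 2.0 / 3.0, "high": 1.0}

#: Onset delay (hours) of the in vivo response relative to in vitro.
VIVO_DELAY_H = 2.0


@dataclass(frozen=True)
class SimulationDesign:
    """Size, noise and shift parameters of a simulated study.

    Defaults reproduce the reference exposure design: 45 compounds, four dose
    levels, in vitro grid (2, 8, 24 h) with 2 replicates, in vivo grid
    (3, 6, 9, 24 h) with 3 replicates. ``noise_sd`` is replicate noise on the
    normalized [0, 1] expression scale; ``domain_shift_magnitude`` sets the
    size of the systematic rat-to-human in vitro shift.
    """

    n_compounds: int = 45
    gene_count: int = 76
    vitro_times: tuple[float, ...] = VITRO_TIMES
    vivo_times: tuple[float, ...] = VIVO_TIMES
    vitro_replicates: int = 2
    vivo_replicates: int = 3
    dose_levels: tuple[str, ...] = DOSES
    noise_sd: float = 0.02
    domain_shift_magnitude: float = 0.3
    discordant_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_compounds < 1:
            raise ValueError("n_compounds must be positive")
        if self.gene_count < 1:
            raise ValueError("gene_count must be positive")
        if self.noise_sd < 0 or self.domain_shift_magnitude < 0:
            raise ValueError("noise_sd and domain_shift_magnitude must be >= 0")

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(f"cmpd{str(i + 1).zfill(3)}" for i in range(self.n_compounds))

    @property
    def gene_set(self) -> GeneSet:
        return GeneSet(
            name=f"synthetic_{self.gene_count}",
            genes=tuple(f"gene{str(i + 1).zfill(4)}" for i in range(self.gene_count)),
        )


@dataclass
class GroundTruth:
    """Noise-free response parameters sufficient to regenerate any trajectory."""

    design: SimulationDesign
    baseline: np.ndarray          # (G,) gene baselines
    amplitude: np.ndarray         # (C, G) signed response amplitudes
    peak_time: np.ndarray         # (C, G) impulse peak times, hours
    vivo_gain: np.ndarray         # (G,) gene-specific in vivo gain
    human_offset: np.ndarray      # (G,) gene-wise additive rat->human shift
    human_gain: np.ndarray        # (G,) gene-wise multiplicative rat->human shift
    discordant: dict = field(default_factory=dict)  # (compound, dose) -> bool

    def _impulse(self, compound_idx: int, dose: str, times: np.ndarray) -> np.ndarray:
        """Latent response matrix (G x T) for one compound-dose on a time grid."""
        w = DOSE_WEIGHTS[dose]
        tau = self.peak_time[compound_idx][:, None]  # (G,1)
        t = np.asarray(times, dtype=float)[None, :]
        shape = (t / tau) * np.exp(1.0 - t / tau)  # peaks at 1 when t == tau
        return w * self.amplitude[compound_idx][:, None] * shape

    def vitro_trajectory(self, compound: str, dose: str, domain: str = RAT_VITRO) -> np.ndarray:
        """Noise-free genes x times in vitro trajectory on the in vitro grid."""
        ci = self.design.compounds.index(compound)
        times = np.asarray(self.design.vitro_times)
        latent = self.baseline[:, None] + self._impulse(ci, dose, times)
        if domain == RAT_VITRO:
            return np.clip(latent, 0.0, 1.0)
        if domain == HUMAN_VITRO:
            shifted = self.human_offset[:, None] + self.human_gain[:, None] * latent
            return np.clip(shifted, 0.0, 1.0)
        raise ValueError(f"not an in vitro domain: {domain!r}")

    def vivo_trajectory(self, compound: str, dose: str) -> np.ndarray:
        """Noise-free genes x times rat in vivo trajectory on the in vivo grid."""
        ci = self.design.compounds.index(compound)
        times = np.maximum(np.asarray(self.design.vivo_times) - VIVO_DELAY_H, 0.0)
        resp = self._impulse(ci, dose, times)
        traj = self.baseline[:, None] + self.vivo_gain[:, None] * resp
        return np.clip(traj, 0.0, 1.0)

    def to_flat_dict(self) -> dict[str, float]:
        """Flat key-value view (one parameter per line when written) for audit."""
        out: dict[str, float] = {}
        genes = self.design.gene_set.genes
        compounds = self.design.compounds
        for g, gene in enumerate(genes):
            out[f"baseline.{gene}"] = float(self.baseline[g])
            out[f"vivo_gain.{gene}"] = float(self.vivo_gain[g])
            out[f"human_offset.{gene}"] = float(self.human_offset[g])
            out[f"human_gain.{gene}"] = float(self.human_gain[g])
        for c, cmpd in enumerate(compounds):
            for g, gene in enumerate(genes):
                out[f"amplitude.{cmpd}.{gene}"] = float(self.amplitude[c, g])
                out[f"peak_time.{cmpd}.{gene}"] = float(self.peak_time[c, g])
        return out

    def write_flat(self, path) -> None:
        with open(path, "wt", encoding="utf-8") as fh:
            for k, v in self.to_flat_dict().items():
                fh.write(f"{k}\t{v:.10g}\n")


def draw_ground_truth(design: SimulationDesign) -> GroundTruth:
    """Sample response parameters for a design (deterministic in design.seed)."""
    rng = np.random.default_rng(np.random.SeedSequence(design.seed).spawn(2)[0])
    G, C = design.gene_count, design.n_compounds
    m = design.domain_shift_magnitude
    truth = GroundTruth(
        design=design,
        baseline=rng.uniform(0.25, 0.55, size=G),
        amplitude=rng.uniform(-0.3, 0.3, size=(C, G)),
        peak_time=rng.uniform(3.0, 18.0, size=(C, G)),
        vivo_gain=rng.uniform(0.6, 1.4, size=G),
        human_offset=m * rng.uniform(-1.0, 1.0, size=G),
        human_gain=1.0 + m * rng.uniform(-0.5, 0.5, size=G),
    )
    if design.discordant_fraction > 0:
        pairs = [(c, d) for c in design.compounds for d in design.dose_levels]
        n_bad = int(round(design.discordant_fraction * len(pairs)))
        bad = rng.choice(len(pairs), size=n_bad, replace=False)
        truth.discordant = {pairs[i]: True for i in bad}
    return truth


def dataset_from_truth(truth: GroundTruth, noise_seed: int | None = None) -> ExposureDataset:
    """Regenerate the replicate-level dataset from ground truth.

    With ``noise_sd == 0`` in the design, the output equals the noise-free
    trajectories exactly, making this the regeneration oracle for tests.
    """
    design = truth.design
    seed = design.seed if noise_seed is None else noise_seed
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    gene_set = design.gene_set
    series = []

    def noisy(traj: np.ndarray) -> np.ndarray:
        if design.noise_sd == 0:
            return traj.copy()
        return np.clip(traj + rng.normal(0.0, design.noise_sd, size=traj.shape), 0.0, 1.0)

    for compound in design.compounds:
        for dose in design.dose_levels:
            rat_traj = truth.vitro_trajectory(compound, dose, RAT_VITRO)
            human_traj = truth.vitro_trajectory(compound, dose, HUMAN_VITRO)
            vivo_traj = truth.vivo_trajectory(compound, dose)
            for rep in range(1, design.vitro_replicates + 1):
                series.append(ExposureSeries(RAT_VITRO, compound, dose, rep,
                                             gene_set.genes, noisy(rat_traj)))
            for rep in range(1, design.vitro_replicates + 1):
                series.append(ExposureSeries(HUMAN_VITRO, compound, dose, rep,
                                             gene_set.genes, noisy(human_traj)))
            discordant = truth.discordant.get((compound, dose), False)
            for rep in range(1, design.vivo_replicates + 1):
                traj = vivo_traj
                if discordant and rep == 2:
                    # Contradictory replicate: the compound response is inverted.
                    ci = design.compounds.index(compound)
                    times = np.maximum(np.asarray(design.vivo_times) - VIVO_DELAY_H, 0.0)
                    resp = truth._impulse(ci, dose, times)
                    traj = np.clip(
                        truth.baseline[:, None] - truth.vivo_gain[:, None] * resp,
                        0.0, 1.0,
                    )
                series.append(ExposureSeries(RAT_VIVO, compound, dose, rep,
                                             gene_set.genes, noisy(traj)))
    return ExposureDataset(gene_set=gene_set, series=series)


def simulate_dataset(design: SimulationDesign) -> tuple[ExposureDataset, GroundTruth]:
    """Simulate a complete multi-domain dataset; bit-identical for equal (design, seed)."""
    truth = draw_ground_truth(design)
    return dataset_from_truth(truth), truth


def assign_toxicity_labels(
    truth: GroundTruth,
    fraction_positive: float,
    seed: int,
    perturbation_magnitude: float = 0.15,
    unknown_fraction: float = 0.0,
) -> tuple[dict[str, str], GroundTruth]:
    """Label compounds positive/negative/unknown and perturb positive responses.

    Positive compounds receive a shared gene-wise amplitude perturbation of the
    given magnitude, so that latent-space separability of the classes is
    attainable; with magnitude 0 the labels carry no signal. A
    ``unknown_fraction`` of compounds is relabelled ``unknown`` (their response
    parameters keep any perturbation already applied), emulating studies where
    toxicity annotations exist for only a subset of compounds.
    """
    if not 0.0 < fraction_positive < 1.0:
        raise ValueError("fraction_positive must be in (0, 1)")
    design = truth.design
    rng = np.random.default_rng(seed)
    compounds = list(design.compounds)
    n_pos = int(round(fraction_positive * len(compounds)))
    pos_idx = set(rng.choice(len(compounds), size=n_pos, replace=False).tolist())
    direction = rng.uniform(-1.0, 1.0, size=design.gene_count)

    amplitude = truth.amplitude.copy()
    labels: dict[str, str] = {}
    for i, compound in enumerate(compounds):
        if i in pos_idx:
            labels[compound] = "positive"
            amplitude[i] = amplitude[i] + perturbation_magnitude * direction
        else:
            labels[compound] = "negative"
    if unknown_fraction > 0:
        n_unknown = int(round(unknown_fraction * len(compounds)))
        unk = rng.choice(len(compounds), size=n_unknown, replace=False)
        for i in unk:
            labels[compounds[i]] = "unknown"

    perturbed = replace(truth, amplitude=amplitude)
    return labels, perturbed


def labelled_compounds(labels: dict[str, str]) -> dict[str, str]:
    """Drop ``unknown`` entries; raise when no labelled compounds remain."""
    known = {c: l for c, l in labels.items() if l in ("positive", "negative")}
    if not known:
        raise NoLabelledCompoundsError("no labelled compounds")
    return known
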