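"""Synthetic qPCR plate generator with known ground truth.

The generator embodies the distributional model the analysis assumes:
relative expression is lognormal, so all noise is Gaussian on the log10
scale.  Per biological sample, the true normalized log10 expression is

    x[r, t] = offset[t] + biological noise + plate shift

with the plate shift shared by every well on a plate (the structure a
randomized complete block removes).  Per-well quantification cycles are
produced by inverting the efficiency weighting, ``Cq = w / log10(E)`` with
``w`` the target weighted value plus technical noise and ``E`` a truncated-
Gaussian per-well efficiency — so the analysis pipeline's estimand equals
the configured truth exactly, and Monte-Carlo checks of bias, coverage and
power are meaningful.  Reference genes do not respond to the sample type
(their role is normalization) unless ``ref_response`` is raised to probe
robustness.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.stats as st
import yaml

from cbqpcr.io import ExperimentTable, ROLE_REFERENCE, ROLE_TARGET

#: Baseline weighted-Cq level of the gene of interest (log10 units); the
#: worked single-plate example sits near 8.4.
GOI_BASE_LEVEL = 8.4
#: Baseline weighted-Cq level of the first reference gene; further
#: references are offset by 0.2 each.
REF_BASE_LEVEL = 7.1
REF_LEVEL_STEP = 0.2


@dataclasses.dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic experiment.

    ``sample_types`` maps each condition label to its true log10
    relative-expression offset; the default pair reproduces a true
    expression ratio of 10^0.546 ≈ 3.52 for A vs. B, the effect size of
    the worked examples.  Standard deviations are log10-scale:
    ``sd_biological`` per biological sample, ``sd_plate`` as an additive
    shift shared by all wells of a plate, ``sd_technical`` per well.
    """

    sample_types: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"A": 0.0, "B": -0.546}
    )
    n_replicates: int = 4
    design: str = "unpaired"  # unpaired | paired
    n_plates: int = 1
    sd_biological: float = 0.15
    sd_plate: float = 0.15
    sd_technical: float = 0.05
    n_technical: int = 3
    efficiency_mean: float = 1.9
    efficiency_sd: float = 0.03
    n_ref_genes: int = 2
    ref_response: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sample_types) < 2:
            raise ValueError("need >= 2 sample types")
        if self.design not in ("unpaired", "paired"):
            raise ValueError(f"unknown design {self.design!r}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_plates < 1 or self.n_plates > self.n_replicates:
            raise ValueError(
                f"n_plates must be in [1, n_replicates]; got {self.n_plates} "
                f"plates for {self.n_replicates} replicates"
            )
        for name in ("sd_biological", "sd_plate", "sd_technical"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0.0):
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        if self.n_technical < 1:
            raise ValueError("n_technical must be >= 1")
        if not (1.0 < self.efficiency_mean <= 2.2):
            raise ValueError(
                f"efficiency_mean must be in (1, 2.2], got {self.efficiency_mean}"
            )
        if self.efficiency_sd < 0.0:
            raise ValueError("efficiency_sd must be >= 0")
        if self.n_ref_genes < 1:
            raise ValueError("n_ref_genes must be >= 1")
        for t, off in self.sample_types.items():
            if not math.isfinite(off):
                raise ValueError(f"offset for {t!r} must be finite, got {off}")
        object.__setattr__(self, "sample_types", dict(self.sample_types))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        loaded = yaml.safe_load(Path(path).read_text(encoding="utf-8"))
        if not isinstance(loaded, Mapping):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls(**loaded)


@dataclasses.dataclass(frozen=True)
class GroundTruth:
    """What the generator actually put into a simulated experiment."""

    config: SimulationConfig
    true_ddcq: dict[tuple[str, str], float]
    true_ratio: dict[tuple[str, str], float]
    sample_truth: pd.DataFrame  # replicate, sample_type, plate, true_delta_cq

    def to_dict(self) -> dict:
        return {
            "config": dataclasses.asdict(self.config),
            "true_ddcq": {f"{a} vs {b}": v for (a, b), v in self.true_ddcq.items()},
            "true_ratio": {
                f"{a} vs {b}": v for (a, b), v in self.true_ratio.items()
            },
            "sample_truth": self.sample_truth.to_dict(orient="records"),
        }


def _draw_efficiencies(
    rng: np.random.Generator, n: int, mean: float, sd: float
) -> np.ndarray:
    if sd == 0.0:
        return np.full(n, mean)
    lo, hi = (1.0 + 1e-9 - mean) / sd, (2.2 - mean) / sd
    return st.truncnorm.rvs(lo, hi, loc=mean, scale=sd, size=n, random_state=rng)


def simulate_experiment(
    config: SimulationConfig,
) -> tuple[ExperimentTable, GroundTruth]:
    """Generate one per-well experiment table plus its ground truth.

    Deterministic for a fixed ``config.seed``.  Plate assignment is by
    replicate index (``plate = r mod n_plates``) for both designs, so every
    plate is a complete block containing every sample type.
    """
    rng = np.random.default_rng(config.seed)
    types = list(config.sample_types)
    n_rep = config.n_replicates
    plate_shift = rng.normal(0.0, config.sd_plate, config.n_plates)

    ref_levels = [
        REF_BASE_LEVEL + REF_LEVEL_STEP * j for j in range(config.n_ref_genes)
    ]
    ref_mean = float(np.mean(ref_levels))

    rows: dict[str, list] = {k: [] for k in (
        "replicate", "sample_type", "gene", "role", "plate", "well",
        "efficiency", "cq",
    )}
    truth_rows = []
    well_counter = 0
    for r in range(n_rep):
        plate_idx = r % config.n_plates
        for t in types:
            offset = config.sample_types[t]
            bio = rng.normal(0.0, config.sd_biological)
            true_dcq = -(offset + bio) + plate_shift[plate_idx]
            truth_rows.append(
                {
                    "replicate": f"r{r + 1}",
                    "sample_type": t,
                    "plate": f"plate{plate_idx + 1}",
                    "true_delta_cq": true_dcq,
                }
            )
            gene_levels = [("goi", ROLE_TARGET, ref_mean + true_dcq)]
            for j, lvl in enumerate(ref_levels):
                gene_levels.append(
                    (f"ref{j + 1}", ROLE_REFERENCE, lvl - config.ref_response * offset)
                )
            for gene, role, level in gene_levels:
                eff = _draw_efficiencies(
                    rng, config.n_technical, config.efficiency_mean,
                    config.efficiency_sd,
                )
                tech = rng.normal(0.0, config.sd_technical, config.n_technical)
                w = level + tech
                cq = w / np.log10(eff)
                for i in range(config.n_technical):
                    well_counter += 1
                    rows["replicate"].append(f"r{r + 1}")
                    rows["sample_type"].append(t)
                    rows["gene"].append(gene)
                    rows["role"].append(role)
                    rows["plate"].append(f"plate{plate_idx + 1}")
                    rows["well"].append(f"w{well_counter}")
                    rows["efficiency"].append(float(eff[i]))
                    rows["cq"].append(float(cq[i]))

    data = pd.DataFrame(rows)
    table = ExperimentTable(
        data=data, goi="goi", refs=tuple(f"ref{j + 1}" for j in range(config.n_ref_genes))
    )

    true_ddcq = {}
    true_ratio = {}
    for i, a in enumerate(types):
        for b in types[i + 1 :]:
            dd = config.sample_types[b] - config.sample_types[a]
            true_ddcq[(a, b)] = dd
            true_ratio[(a, b)] = 10.0 ** (-dd)
    truth = GroundTruth(
        config=config,
        true_ddcq=true_ddcq,
        true_ratio=true_ratio,
        sample_truth=pd.DataFrame(truth_rows),
    )
    return table, truth
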