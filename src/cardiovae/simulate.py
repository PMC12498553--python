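"""Synthetic paired metabolome/transcriptome generator.

Emulates the study design the analysis assumes: six exercise conditions
(A = rest, B = low intensity, C = moderate, D = high-intensity interval,
E = prolonged low intensity, F = intermittent high intensity), ten animals
per condition, with paired per-sample measurements of 15 cardiac
metabolites (concentration units) and 20 energy-metabolism / autophagy
genes (TPM).

Group means for the six energy metabolites (ATP, ADP, AMP, NADH, NAD+,
NADP) are anchored to the measured per-condition concentrations; SIRT1
expression is anchored to the measured rest/high-intensity TPM values.
The remaining features use plausible baselines with condition effects
oriented by the underlying physiology (lactate and HIF1A rise with
intensity, glucose and MTOR fall, fatty-acid-oxidation genes peak under
prolonged low-intensity work, p62/SQSTM1 falls as autophagy increases).

Noise is multiplicative log-normal: metabolite concentrations and TPMs
are positive and right-skewed, so a sample is drawn as
``group_mean * exp(N(-sigma^2/2, sigma^2))`` with
``sigma = sqrt(ln(1 + cv^2))``.  The -sigma^2/2 centring gives the
multiplicative noise unit mean, so empirical group means converge to the
configured means.  Batch effects are applied on the log scale as a
per-batch location/scale distortion — exactly the model that parametric
empirical-Bayes batch correction assumes and removes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io as cio

GROUPS: tuple[str, ...] = ("A", "B", "C", "D", "E", "F")

# Six energy metabolites, group means in umol/L (A..F).
_ENERGY_METABOLITES = {
    "ATP": (20, 22, 25, 27, 24, 26),
    "ADP": (15, 14, 12, 10, 13, 11),
    "AMP": (5, 6, 7, 8, 6, 7),
    "NADH": (25, 23, 20, 18, 22, 21),
    "NAD+": (20, 21, 22, 25, 23, 24),
    "NADP": (10, 11, 12, 13, 11, 12),
}

# Glycolysis / TCA metabolites: per-condition means in umol/L.  Each
# condition carries a distinctive signature: lactate/pyruvate rise with
# intensity (anaerobic work, peaking in D and F), glucose falls most
# under prolonged exercise (glycogen depletion in E), TCA intermediates
# rise moderately with workload.
_OTHER_METABOLITES = {
    "Glucose": (5000, 4600, 4100, 3400, 3000, 3700),
    "Lactate": (1500, 1900, 2400, 3600, 1700, 3100),
    "Pyruvate": (150, 170, 230, 260, 160, 240),
    "Citrate": (400, 430, 480, 540, 500, 520),
    "Malate": (300, 330, 370, 420, 390, 400),
    "Succinate": (200, 225, 260, 320, 240, 290),
    "Fumarate": (80, 86, 96, 112, 90, 104),
    "Isocitrate": (30, 32, 35, 39, 33, 37),
    "Alpha-Ketoglutarate": (25, 24, 22, 19, 21, 20),
}

# 20-gene panel (TPM means, A..F). SIRT1 anchored at rest=4.2, high=6.8.
# Fatty-acid-oxidation genes (Cpt1b, Pdk4, Ppara) peak under prolonged
# low-intensity work (E); glycolytic/hypoxic genes (Ldh, Hif1a) and
# autophagy/mitophagy genes (Atg5, Pink1) peak under high intensity
# (D, F); p62/Sqstm1 falls as autophagic flux rises.
_GENES = {
    "Pgc1a": (40, 47, 54, 62, 58, 57),
    "Atg5": (25, 29, 35, 44, 32, 41),
    "Ldh": (300, 330, 390, 480, 320, 440),
    "Ucp2": (60, 65, 72, 82, 76, 78),
    "Cpt1b": (120, 140, 150, 128, 185, 138),
    "Ampk": (80, 92, 106, 128, 110, 120),
    "Foxo1": (50, 55, 62, 72, 64, 68),
    "Pdk4": (30, 42, 46, 36, 58, 40),
    "Ppara": (70, 78, 83, 76, 96, 79),
    "Ppargc1b": (20, 22, 25, 28, 26, 27),
    "Mtor": (45, 42, 38, 32, 36, 34),
    "Sirt1": (4.2, 4.8, 5.6, 6.8, 5.2, 6.2),
    "Hif1a": (35, 38, 45, 58, 37, 52),
    "Cox1": (500, 520, 548, 580, 560, 565),
    "Cox2": (450, 470, 494, 520, 505, 508),
    "Cox3": (480, 498, 520, 548, 532, 536),
    "Mfn2": (90, 96, 102, 110, 105, 107),
    "Drp1": (75, 81, 90, 102, 84, 96),
    "Pink1": (40, 46, 54, 66, 48, 60),
    "Sqstm1": (55, 49, 43, 34, 46, 37),
}


def default_metabolite_means() -> pd.DataFrame:
    """Default group × metabolite mean table (15 metabolites, umol/L)."""
    cols = {**_ENERGY_METABOLITES, **_OTHER_METABOLITES}
    return pd.DataFrame(cols, index=list(GROUPS), dtype=float)


def default_gene_means() -> pd.DataFrame:
    """Default group × gene mean table (20 genes, TPM)."""
    return pd.DataFrame(_GENES, index=list(GROUPS), dtype=float)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated study.

    ``batch_shift`` / ``batch_scale`` act on the natural-log scale:
    log-values of a sample in batch b become ``scale_b * log(v) + shift_b``.
    """

    n_per_group: int = 10
    groups: tuple[str, ...] = GROUPS
    metabolite_means: pd.DataFrame = field(default_factory=default_metabolite_means)
    gene_means: pd.DataFrame = field(default_factory=default_gene_means)
    noise_cv: float = 0.1
    batch_assignment: Mapping[str, str] | None = None
    batch_shift: Mapping[str, float] | None = None
    batch_scale: Mapping[str, float] | None = None
    metabolite_units: str = "umol/L"
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 1:
            raise ConfigurationError("n_per_group must be >= 1")
        if self.noise_cv < 0:
            raise ConfigurationError("noise_cv must be >= 0")
        for name, table in (("metabolite", self.metabolite_means),
                            ("gene", self.gene_means)):
            missing = [g for g in self.groups if g not in table.index]
            if missing:
                raise ConfigurationError(
                    f"missing {name} mean vector for group(s) {missing}"
                )
            if table.isna().any().any():
                raise ConfigurationError(f"{name} mean table contains NaN")
        if (self.metabolite_means.loc[list(self.groups)] <= 0).any().any():
            raise ConfigurationError("metabolite means must be > 0")
        if self.batch_scale is not None and any(
            s <= 0 for s in self.batch_scale.values()
        ):
            raise ConfigurationError("batch_scale factors must be > 0")


@dataclass
class OmicsDataset:
    """Paired metabolite (x) and expression (y) matrices with annotations.

    Rows of ``x`` and ``y`` are aligned sample-by-sample; ``group`` and
    ``batch`` are per-sample labels indexed like the matrices.
    """

    x: pd.DataFrame
    y: pd.DataFrame
    group: pd.Series
    batch: pd.Series
    metabolite_units: str = "umol/L"

    def __post_init__(self) -> None:
        if not self.x.index.equals(self.y.index):
            raise ValueError("x and y must share the same sample index")
        if len(set(self.x.columns)) != self.x.shape[1]:
            raise ValueError("metabolite names are not unique")
        if len(set(self.y.columns)) != self.y.shape[1]:
            raise ValueError("gene names are not unique")
        if (self.x.values < 0).any() or (self.y.values < 0).any():
            raise ValueError("concentrations and TPMs cannot be negative")

    @property
    def sample_ids(self) -> pd.Index:
        return self.x.index

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]

    def copy(self) -> "OmicsDataset":
        return OmicsDataset(
            self.x.copy(), self.y.copy(), self.group.copy(), self.batch.copy(),
            self.metabolite_units,
        )

    # -- delimited-text round trip ------------------------------------
    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        cio.write_matrix(self.x, path / "metabolites.tsv")
        cio.write_matrix(self.y, path / "expression.tsv")
        ann = pd.DataFrame({"group": self.group, "batch": self.batch})
        cio.write_annotations(ann, path / "samples.tsv")

    @classmethod
    def from_dir(cls, path: str | Path,
                 metabolite_units: str = "umol/L") -> "OmicsDataset":
        path = Path(path)
        x = cio.read_matrix(path / "metabolites.tsv")
        y = cio.read_matrix(path / "expression.tsv")
        ann = cio.read_annotations(path / "samples.tsv")
        batch = ann["batch"] if "batch" in ann.columns else pd.Series(
            "batch0", index=ann.index
        )
        return cls(x, y, ann["group"], batch, metabolite_units)


def _lognormal_sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def generate_dataset(config: SimConfig | None = None) -> OmicsDataset:
    """Draw one paired dataset from the configured study design.

    Each sample is its group-mean vector times unit-mean log-normal noise
    with coefficient of variation ``noise_cv``; batch location/scale
    effects, if configured, are then applied on the log scale.  Fully
    reproducible from ``config.seed``.
    """
    if config is None:
        config = SimConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    sigma = _lognormal_sigma(config.noise_cv)

    met_names = list(config.metabolite_means.columns)
    gene_names = list(config.gene_means.columns)
    sample_ids, groups = [], []
    x_rows, y_rows = [], []
    for g in config.groups:
        mu_x = config.metabolite_means.loc[g, met_names].to_numpy(float)
        mu_y = config.gene_means.loc[g, gene_names].to_numpy(float)
        for i in range(config.n_per_group):
            sample_ids.append(f"{g}{i + 1:02d}")
            groups.append(g)
            if sigma > 0:
                nx = np.exp(rng.normal(-0.5 * sigma**2, sigma, mu_x.size))
                ny = np.exp(rng.normal(-0.5 * sigma**2, sigma, mu_y.size))
            else:
                nx = np.ones(mu_x.size)
                ny = np.ones(mu_y.size)
            x_rows.append(mu_x * nx)
            y_rows.append(mu_y * ny)

    idx = pd.Index(sample_ids, name="sample_id")
    x = pd.DataFrame(np.array(x_rows), index=idx, columns=met_names)
    y = pd.DataFrame(np.array(y_rows), index=idx, columns=gene_names)
    group = pd.Series(groups, index=idx, name="group")

    if config.batch_assignment is not None:
        batch = pd.Series(
            [config.batch_assignment[s] for s in idx], index=idx, name="batch"
        )
    else:
        batch = pd.Series("batch0", index=idx, name="batch")

    data = OmicsDataset(x, y, group, batch, config.metabolite_units)
    if config.batch_shift or config.batch_scale:
        shifts = dict(config.batch_shift or {})
        scales = dict(config.batch_scale or {})
        labels = set(batch)
        shift = {b: shifts.get(b, 0.0) for b in labels}
        scale = {b: scales.get(b, 1.0) for b in labels}
        data = inject_batch_effects(data, shift, scale, dict(zip(idx, batch)))
    return data


def inject_batch_effects(
    data: OmicsDataset,
    shift: Mapping[str, float],
    scale: Mapping[str, float],
    assignment: Mapping[str, str],
) -> OmicsDataset:
    """Apply per-batch log-scale location/scale distortion; returns a copy.

    For a sample in batch b, every value v becomes
    ``exp(scale_b * log(v) + shift_b)``.
    """
    missing_samples = [s for s in data.sample_ids if s not in assignment]
    if missing_samples:
        raise ConfigurationError(
            f"samples without batch assignment: {missing_samples[:5]}"
        )
    for s in data.sample_ids:
        b = assignment[s]
        if b not in shift or b not in scale:
            raise ConfigurationError(f"unknown batch label {b!r}")
        if scale[b] <= 0:
            raise ConfigurationError(f"batch_scale for {b!r} must be > 0")

    out = data.copy()
    batches = pd.Series({s: assignment[s] for s in data.sample_ids})
    for mat in (out.x, out.y):
        logv = np.log(mat.to_numpy(float))
        for b in batches.unique():
            rows = (batches.loc[mat.index] == b).to_numpy()
            logv[rows] = scale[b] * logv[rows] + shift[b]
        mat.iloc[:, :] = np.exp(logv)
    out.batch = pd.Series(batches.loc[out.x.index].to_numpy(),
                          index=out.x.index, name="batch")
    return out


def with_two_batches(config: SimConfig, shift: float = 0.5,
                     scale: float = 1.0) -> SimConfig:
    """Convenience: split samples alternately into two batches with a known
    log-scale shift/scale on the second batch."""
    ids = [f"{g}{i + 1:02d}" for g in config.groups
           for i in range(config.n_per_group)]
    assignment = {s: ("batch1" if k % 2 == 0 else "batch2")
                  for k, s in enumerate(ids)}
    return replace(
        config,
        batch_assignment=assignment,
        batch_shift={"batch1": 0.0, "batch2": shift},
        batch_scale={"batch1": 1.0, "batch2": scale},
    )
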