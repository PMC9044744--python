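"""Synthetic formulation and descriptor tables with known ground truth.

The generator emulates the structure of a curated directly-compressed ODT
database so that every pipeline stage can be tested without downloading the
deposited data: zero-inflated, right-skewed excipient composition columns
(most formulations contain mannitol; few contain camphor), a tablet-mass /
punch-die correlation induced by cylinder geometry, manufacturing parameters
confined to the curated database's min/max envelope, and 26 synthetic APIs
carrying an XLogP-like lipophilicity descriptor.

The target is generated from a documented mechanism so feature-selection and
explanation stages have ground truth to recover:

    t = b0 + sum_d beta_d * disintegrant_d[%]          (negative betas)
        + beta_hard * max(0, hardness - 100 N)          (hinge: very hard
                                                         tablets disintegrate
                                                         slowly)
        + beta_lip * XLogP                              (lipophilic APIs slow
                                                         wetting)
        + beta_int * XLogP * total_disintegrant[%]      (disintegrants less
                                                         effective for
                                                         lipophilic APIs)
        + eps,   eps ~ N(0, noise_sd)

clipped below at 3 s. The defaults put roughly 5% of records past the
180-second pharmacopoeial limit so the exclusion filter is exercised.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ContractError
from .io import FormulationTable

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "generate_formulations",
    "generate_descriptor_table",
    "generate_dataset",
    "EXCIPIENTS",
]

#: (presence probability, max mass %) per excipient, mirroring the occupancy
#: pattern and envelope of the curated database. Fillers (mannitol, MCC) are
#: handled separately: they absorb the mass balance up to 100%.
EXCIPIENTS: dict[str, tuple[float, float]] = {
    "Lactose [%]": (0.20, 62.0),
    "SSG [%]": (0.25, 18.21),
    "CC-Na [%]": (0.60, 31.95),
    "Crospovidone [%]": (0.45, 20.03),
    "L-HPC [%]": (0.08, 14.71),
    "Pregelatinized starch [%]": (0.04, 5.08),
    "Sodium carboxymethyl starch [%]": (0.02, 5.0),
    "2-HP-beta-CD [%]": (0.12, 36.46),
    "beta-CD [%]": (0.05, 9.31),
    "CD-methacrylate [%]": (0.02, 11.39),
    "Amberlite [%]": (0.05, 8.35),
    "Eudragit EPO [%]": (0.05, 61.54),
    "Poloxamer [%]": (0.07, 7.95),
    "PVP [%]": (0.15, 7.99),
    "SLS [%]": (0.06, 2.16),
    "PVA [%]": (0.03, 4.52),
    "Camphor [%]": (0.10, 10.31),
    "MgSt [%]": (0.70, 3.0),
    "Aerosil [%]": (0.30, 2.0),
    "Colloidal silica [%]": (0.10, 2.0),
    "Talc [%]": (0.15, 5.0),
    "SSF [%]": (0.08, 3.0),
    "HPMC [%]": (0.08, 5.0),
    "Calcium silicate [%]": (0.05, 10.0),
    "Sodium bicarbonate [%]": (0.05, 10.0),
}

_FILLERS = {"Mannitol [%]": (0.85, 86.84), "MCC [%]": (0.75, 84.1)}

_ENVELOPE = {
    "Tablet mass [mg]": (67.13, 1179.98),
    "Thickness [mm]": (1.86, 6.5),
    "Punch die of tablet press [mm]": (5.5, 16.0),
    "Hardness [N]": (2.4, 155.43),
}

_XLOGP_RANGE = (1.14, 10.61)


def _default_coefficients() -> dict[str, float]:
    return {"CC-Na [%]": -2.5, "Crospovidone [%]": -3.0, "SSG [%]": -3.0}


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic database.

    The coefficients, hinge location and noise level are the generator's
    documented mechanism (see module docstring); ``noise_sd`` is in seconds.
    """

    n: int = 250
    seed: int = 0
    n_apis: int = 26
    n_descriptors: int = 50
    n_informative_descriptors: int = 3
    intercept: float = 63.0
    coefficients: dict[str, float] = field(default_factory=_default_coefficients)
    beta_hardness: float = 5.0
    hardness_hinge: float = 100.0
    beta_lipophilicity: float = 9.0
    beta_interaction: float = 0.15
    noise_sd: float = 8.0
    clip_min: float = 3.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ContractError("noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """The generating mechanism, regenerable from the seed."""

    intercept: float
    coefficients: dict[str, float]
    beta_hardness: float
    hardness_hinge: float
    beta_lipophilicity: float
    beta_interaction: float
    noise_sd: float
    seed: int
    informative_features: list[str]
    noiseless_target: np.ndarray
    api_lipophilicity: dict[str, float]
    formula: str = (
        "t = b0 + sum_d beta_d*disintegrant_d + beta_hard*max(0, hardness-hinge)"
        " + beta_lip*XLogP + beta_int*XLogP*total_disintegrant + eps"
    )

    def to_json(self, path: str | Path | None = None) -> str:
        d = {
            "intercept": self.intercept,
            "coefficients": self.coefficients,
            "beta_hardness": self.beta_hardness,
            "hardness_hinge": self.hardness_hinge,
            "beta_lipophilicity": self.beta_lipophilicity,
            "beta_interaction": self.beta_interaction,
            "noise_sd": self.noise_sd,
            "seed": self.seed,
            "informative_features": self.informative_features,
            "api_lipophilicity": self.api_lipophilicity,
            "formula": self.formula,
            "noiseless_target": [float(v) for v in self.noiseless_target],
        }
        text = json.dumps(d, indent=2)
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text


def _api_lipophilicity(n_apis: int, seed: int) -> dict[str, float]:
    """Per-API XLogP-like values; shared by formulation and descriptor
    generators so the same seed yields a consistent pair of tables."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(101,)))
    lo, hi = _XLOGP_RANGE
    vals = lo + (hi - lo) * rng.beta(1.8, 3.2, size=n_apis)
    return {f"API-{i + 1:02d}": float(v) for i, v in enumerate(vals)}


def generate_formulations(cfg: GeneratorConfig) -> tuple[FormulationTable, GroundTruth]:
    """Generate ``cfg.n`` formulations plus the ground truth that made them."""
    if cfg.n < 1:
        raise ContractError("n must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=cfg.seed, spawn_key=(1,)))
    n = cfg.n
    lip = _api_lipophilicity(cfg.n_apis, cfg.seed)
    api_names = list(lip)
    api_of = rng.choice(api_names, size=n)

    api_pct = 1.0 + 66.8 * rng.beta(1.1, 6.0, size=n)
    comp: dict[str, np.ndarray] = {"API [%]": api_pct}
    for name, (p_present, max_pct) in EXCIPIENTS.items():
        present = rng.random(n) < p_present
        amounts = max_pct * rng.beta(1.3, 4.0, size=n)
        comp[name] = np.where(present, np.minimum(amounts, max_pct), 0.0)

    others = np.sum([comp[c] for c in EXCIPIENTS], axis=0)
    # rescale non-filler excipients where API + excipients already exceed ~99%
    excess = api_pct + others > 99.0
    if np.any(excess):
        scale = (99.0 - api_pct[excess]) / np.maximum(others[excess], 1e-9)
        scale = np.clip(scale, 0.0, 1.0)
        for c in EXCIPIENTS:
            comp[c][excess] *= scale
        others = np.sum([comp[c] for c in EXCIPIENTS], axis=0)

    remainder = np.maximum(0.0, 100.0 - api_pct - others)
    man_present = rng.random(n) < _FILLERS["Mannitol [%]"][0]
    mcc_present = rng.random(n) < _FILLERS["MCC [%]"][0]
    split = rng.beta(2.0, 2.0, size=n)
    mannitol = np.where(man_present & mcc_present, remainder * split,
                        np.where(man_present, remainder, 0.0))
    mcc = np.where(man_present & mcc_present, remainder * (1 - split),
                   np.where(~man_present & mcc_present, remainder, 0.0))
    # a formulation needs some filler: orphan remainder goes to mannitol
    orphan = ~man_present & ~mcc_present
    mannitol = np.where(orphan, remainder, mannitol)
    # respect the envelope maxima, shifting overflow to the other filler
    man_max, mcc_max = _FILLERS["Mannitol [%]"][1], _FILLERS["MCC [%]"][1]
    over = np.maximum(0.0, mannitol - man_max)
    mannitol -= over
    mcc = np.minimum(mcc + over, mcc_max)
    over = np.maximum(0.0, mcc - mcc_max)
    mcc -= over
    mannitol = np.minimum(mannitol + over, man_max)
    comp["Mannitol [%]"] = mannitol
    comp["MCC [%]"] = mcc

    # manufacturing parameters: mass follows cylinder volume times apparent
    # density, giving the expected mass/punch-die correlation
    die_values = np.array([5.5, 6.0, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 13.0, 16.0])
    die_probs = np.array([0.04, 0.06, 0.16, 0.22, 0.14, 0.16, 0.08, 0.07, 0.04, 0.03])
    die = rng.choice(die_values, size=n, p=die_probs / die_probs.sum())
    thickness = 1.86 + (6.5 - 1.86) * rng.beta(2.2, 4.5, size=n)
    density = np.clip(rng.normal(1.05, 0.12, size=n), 0.8, 1.3)  # mg/mm^3
    volume = np.pi * (die / 2.0) ** 2 * thickness
    mass = np.clip(volume * density, *_ENVELOPE["Tablet mass [mg]"])
    hardness = np.clip(2.4 + rng.gamma(2.2, 22.0, size=n), *_ENVELOPE["Hardness [N]"])

    xlogp = np.array([lip[a] for a in api_of])
    dis_total = sum(comp[c] for c in cfg.coefficients)
    linear = (
        cfg.intercept
        + sum(beta * comp[c] for c, beta in cfg.coefficients.items())
        + cfg.beta_hardness * np.maximum(0.0, hardness - cfg.hardness_hinge)
        + cfg.beta_lipophilicity * xlogp
        + cfg.beta_interaction * xlogp * dis_total
    )
    eps = rng.normal(0.0, cfg.noise_sd, size=n) if cfg.noise_sd > 0 else np.zeros(n)
    target = np.maximum(cfg.clip_min, linear + eps)

    df = pd.DataFrame({"Record ID": [f"S{i + 1:04d}" for i in range(n)],
                       "API name": api_of})
    categories = {"Record ID": "id", "API name": "api"}
    for c in ["API [%]", "Mannitol [%]", "MCC [%]", *EXCIPIENTS]:
        df[c] = comp[c]
        categories[c] = "composition"
    for c, v in {
        "Tablet mass [mg]": mass,
        "Thickness [mm]": thickness,
        "Punch die of tablet press [mm]": die,
        "Hardness [N]": hardness,
    }.items():
        df[c] = v
        categories[c] = "manufacturing"
    df["Disintegration time [s]"] = target
    categories["Disintegration time [s]"] = "target"

    truth = GroundTruth(
        intercept=cfg.intercept,
        coefficients=dict(cfg.coefficients),
        beta_hardness=cfg.beta_hardness,
        hardness_hinge=cfg.hardness_hinge,
        beta_lipophilicity=cfg.beta_lipophilicity,
        beta_interaction=cfg.beta_interaction,
        noise_sd=cfg.noise_sd,
        seed=cfg.seed,
        informative_features=[*cfg.coefficients, "Hardness [N]", "XLogP"],
        noiseless_target=linear,
        api_lipophilicity=lip,
    )
    return FormulationTable(df, categories), truth


def generate_descriptor_table(
    n_apis: int = 26,
    n_descriptors: int = 50,
    n_informative: int = 3,
    seed: int = 0,
    rho: float = 0.9,
) -> tuple[pd.DataFrame, list[str]]:
    """Per-API molecular-descriptor table plus the informative-name list.

    The first column is the XLogP-like lipophilicity axis the target depends
    on; ``n_informative`` further descriptors correlate with it (population
    correlation ``rho``), one column is constant (to exercise degenerate-
    column dropping), and the rest are independent noise. Use the same seed
    as :func:`generate_formulations` for a consistent pair of tables.
    """
    if n_informative + 2 > n_descriptors:
        raise ContractError("n_descriptors must cover XLogP, informative and constant columns")
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2,)))
    lip = _api_lipophilicity(n_apis, seed)
    x = np.array(list(lip.values()))
    z = (x - x.mean()) / x.std()

    data: dict[str, np.ndarray] = {"API name": np.array(list(lip))}
    data["XLogP"] = x
    informative = ["XLogP"]
    for i in range(n_informative):
        noise = rng.normal(size=n_apis)
        corr = rho * z + np.sqrt(1 - rho**2) * noise
        data[f"D_info_{i + 1:02d}"] = 2.0 + 1.5 * corr
        informative.append(f"D_info_{i + 1:02d}")
    data["D_const"] = np.full(n_apis, 1.0)
    n_noise = n_descriptors - n_informative - 2
    for i in range(n_noise):
        data[f"D_noise_{i + 1:02d}"] = rng.normal(0.0, 1.0, size=n_apis)
    return pd.DataFrame(data), informative


def generate_dataset(cfg: GeneratorConfig) -> tuple[FormulationTable, GroundTruth, pd.DataFrame]:
    """Formulations merged with geometry and descriptors: the full model input.

    Convenience wrapper returning ``(enriched table, ground truth, descriptor
    table)``; the constant descriptor column is left in place so downstream
    degenerate-column dropping is exercised.
    """
    from .descriptors import add_geometry_columns, merge_api_descriptors

    table, truth = generate_formulations(cfg)
    desc, _ = generate_descriptor_table(cfg.n_apis, cfg.n_descriptors,
                                        cfg.n_informative_descriptors, seed=cfg.seed)
    table = add_geometry_columns(table)
    table = merge_api_descriptors(table, desc)
    return table, truth, desc
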