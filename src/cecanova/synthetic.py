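"""Synthetic OTU tables with the statistical structure of a multi-farm
16S study.

The generator emulates the features of the real data the downstream
analysis assumes: a fixed design of farm x batch x antibiotic x feeding
cells, log-normal library sizes truncated at a minimum sequencing depth,
a heavy-tailed (log-normal) base composition over OTUs, and
Dirichlet-multinomial counts so that samples are compositional and
overdispersed relative to a plain multinomial. Group effects are planted
multiplicatively on the expected relative abundance of chosen OTUs before
renormalization, and the list of planted effects is returned as ground
truth.

Body-weight trajectories (for average-daily-gain analyses) are simulated
as linear growth plus Gaussian noise at the weekly recording ages.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError
from .io_formats import (
    RANKS,
    UNASSIGNED,
    CountTable,
    TaxonomyMap,
    design_fixture,
    validate_metadata,
)

__all__ = [
    "EffectSpec",
    "SimulationParams",
    "EFFECT_FACTORS",
    "generate_taxonomy",
    "generate_counts",
    "generate_weights",
    "expected_composition",
    "dirichlet_multinomial",
    "two_farm_design",
]

#: Effect factors and the sample group each one multiplies (the
#: complementary group is left at baseline). Directions match the
#: contrasts reported downstream: farm effects multiply farm A samples
#: (A - B estimates), feeding effects multiply restricted samples
#: (R - AL estimates), antibiotic effects multiply antibiotic-free
#: samples (without - with estimates).
EFFECT_FACTORS = ("farm", "feeding_within_A", "feeding_within_B", "antibiotic_within_B")

#: the eight phyla observed in rabbit cecal samples
PHYLA = (
    "Firmicutes", "Tenericutes", "Bacteroidetes", "Actinobacteria",
    "Proteobacteria", "Verrucomicrobia", "Cyanobacteria", "Euryarchaeota",
)
#: rough phylum composition weights (Firmicutes-dominated community)
PHYLUM_WEIGHTS = (0.62, 0.08, 0.10, 0.04, 0.05, 0.04, 0.04, 0.03)

#: the 28 known genera, mapped to their phylum
GENUS_TO_PHYLUM = {
    "Ruminococcus": "Firmicutes", "Blautia": "Firmicutes", "Oscillospira": "Firmicutes",
    "Clostridium": "Firmicutes", "Coprococcus": "Firmicutes", "Dorea": "Firmicutes",
    "Anaerofustis": "Firmicutes", "Anaerostipes": "Firmicutes",
    "Butyrivibrio": "Firmicutes", "Coprobacillus": "Firmicutes",
    "Dehalobacterium": "Firmicutes", "Epulopiscium": "Firmicutes",
    "p-75-a5": "Firmicutes", "Phascolarctobacterium": "Firmicutes",
    "rc4-4": "Firmicutes", "Lactobacillus": "Firmicutes",
    "Anaeroplasma": "Tenericutes",
    "Bacteroides": "Bacteroidetes", "Parabacteroides": "Bacteroidetes",
    "Rikenella": "Bacteroidetes", "Butyricimonas": "Bacteroidetes",
    "Odoribacter": "Bacteroidetes",
    "Adlercreutzia": "Actinobacteria",
    "Campylobacter": "Proteobacteria", "Desulfovibrio": "Proteobacteria",
    "Oxalobacter": "Proteobacteria",
    "Akkermansia": "Verrucomicrobia",
    "Methanobrevibacter": "Euryarchaeota",
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted multiplicative group effect on one OTU."""

    otu_id: str
    factor: str
    log2_fold_change: float

    def __post_init__(self) -> None:
        if self.factor not in EFFECT_FACTORS:
            raise ParameterError(f"unknown effect factor {self.factor!r}")
        if not np.isfinite(self.log2_fold_change):
            raise ParameterError("log2_fold_change must be finite")


@dataclass
class SimulationParams:
    """Parameters of the count generator.

    Defaults emulate the study scale: 963 OTUs over the 425-sample
    design, library sizes log-normal with median ~28k counts (mean ~35k)
    truncated below at 10,157, heavy-tailed base abundances, and a
    Dirichlet concentration of 200 (moderate overdispersion).
    """

    n_otus: int = 963
    design: pd.DataFrame | None = None
    library_log_mean: float = float(np.log(28_000.0))
    library_log_sd: float = 0.7
    min_depth: int = 10_157
    base_log_sd: float = 1.8
    concentration: float = 200.0
    effects: tuple[EffectSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_otus < 1:
            raise ParameterError("n_otus must be positive")
        if self.library_log_sd <= 0 or self.base_log_sd <= 0 or self.concentration <= 0:
            raise ParameterError("scale parameters must be positive")
        if self.min_depth < 1:
            raise ParameterError("min_depth must be >= 1")
        if self.design is None:
            self.design = design_fixture()
        else:
            self.design = validate_metadata(self.design)
        self.effects = tuple(self.effects)
        seen = set()
        for e in self.effects:
            key = (e.otu_id, e.factor)
            if key in seen:
                raise ParameterError(f"duplicate effect for {key}")
            seen.add(key)


def _otu_ids(n: int) -> list[str]:
    return [f"OTU{i + 1:04d}" for i in range(n)]


def generate_taxonomy(n_otus: int, n_phyla: int = 8, n_genera: int = 28,
                      frac_genus_unassigned: float = 0.15,
                      seed: int | None = 0) -> TaxonomyMap:
    """Assign each OTU a nested lineage over ``n_phyla`` phyla and
    ``n_genera`` genera; a fraction of OTUs is left genus-unassigned
    (truncated at family or order level)."""
    if not (1 <= n_phyla <= n_genera):
        raise ParameterError("need n_genera >= n_phyla >= 1")
    if n_otus < n_genera:
        raise ParameterError("n_otus must be >= n_genera")
    rng = np.random.default_rng(seed)

    phyla = list(PHYLA[:n_phyla])
    phyla += [f"Phylum{i + 1:02d}" for i in range(len(phyla), n_phyla)]
    weights = np.asarray(PHYLUM_WEIGHTS[:n_phyla], dtype=float)
    if len(weights) < n_phyla:
        weights = np.concatenate([weights, np.full(n_phyla - len(weights), 0.02)])
    weights /= weights.sum()

    # genera nested within phyla; named genera first, synthetic extras after
    genera: list[tuple[str, str]] = []
    for g, p in GENUS_TO_PHYLUM.items():
        if p in phyla and len(genera) < n_genera:
            genera.append((g, p))
    i = 0
    while len(genera) < n_genera:
        genera.append((f"Genus{i + 1:02d}", phyla[i % n_phyla]))
        i += 1
    genera = genera[:n_genera]

    rows: dict[str, list[str]] = {}
    otus = _otu_ids(n_otus)
    # guarantee every phylum and genus appears at least once
    forced_genus = list(range(n_genera))
    genus_of_phylum: dict[str, list[int]] = {}
    for gi, (g, p) in enumerate(genera):
        genus_of_phylum.setdefault(p, []).append(gi)

    for k, otu in enumerate(otus):
        if k < n_genera:
            gi = forced_genus[k]
            phylum = genera[gi][1]
            genus: str | None = genera[gi][0]
        else:
            phylum = phyla[rng.choice(n_phyla, p=weights)]
            # phyla without any known genus stay genus-unassigned
            if rng.random() < frac_genus_unassigned or phylum not in genus_of_phylum:
                genus = None
            else:
                gi = int(rng.choice(genus_of_phylum[phylum]))
                genus = genera[gi][0]
        pidx = phyla.index(phylum)
        cls = f"Class_{phylum}"
        if genus is None:
            # truncate at order or family level
            depth = int(rng.integers(3, 5))  # 3 -> order assigned, 4 -> family
            order = f"Order_{phylum}_{int(rng.integers(1, 4))}"
            fam = f"Family_{phylum}_{int(rng.integers(1, 6))}" if depth == 4 else UNASSIGNED
            row = ["Bacteria", phylum, cls, order, fam, UNASSIGNED, UNASSIGNED]
        else:
            row = ["Bacteria", phylum, cls, f"Order_of_{genus}",
                   f"Family_of_{genus}", genus, UNASSIGNED]
        rows[otu] = row

    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
    df.index.name = "otu_id"
    return TaxonomyMap(df)


def _effect_masks(design: pd.DataFrame) -> dict[str, np.ndarray]:
    farm = design["farm"].to_numpy()
    feeding = design["feeding"].to_numpy()
    anti = design["antibiotic"].to_numpy()
    return {
        "farm": farm == "A",
        "feeding_within_A": (farm == "A") & (feeding == "R"),
        "feeding_within_B": (farm == "B") & (feeding == "R"),
        "antibiotic_within_B": (farm == "B") & (anti == "without"),
    }


def base_abundances(params: SimulationParams) -> np.ndarray:
    """Heavy-tailed base composition over OTUs (deterministic in the seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 11]))
    raw = rng.lognormal(mean=0.0, sigma=params.base_log_sd, size=params.n_otus)
    return raw / raw.sum()


def expected_composition(params: SimulationParams) -> pd.DataFrame:
    """Expected relative abundance of every OTU in every sample.

    Rows are OTUs, columns are sample ids. This is the exact mean of the
    per-sample Dirichlet composition, i.e. the planted ground truth on the
    relative-abundance scale.
    """
    design = params.design
    base = base_abundances(params)
    otus = _otu_ids(params.n_otus)
    otu_index = {o: i for i, o in enumerate(otus)}
    masks = _effect_masks(design)
    n = len(design)
    comp = np.tile(base[:, None], (1, n))
    for e in params.effects:
        if e.otu_id not in otu_index:
            raise ParameterError(f"effect references unknown OTU {e.otu_id!r}")
        comp[otu_index[e.otu_id], masks[e.factor]] *= 2.0 ** e.log2_fold_change
    comp /= comp.sum(axis=0, keepdims=True)
    return pd.DataFrame(comp, index=otus, columns=list(design["sample_id"]))


def dirichlet_multinomial(rng: np.random.Generator, mean_comp: np.ndarray,
                          concentration: float, n: int) -> np.ndarray:
    """One Dirichlet-multinomial draw with E[count_i] = n * mean_comp_i."""
    alpha = np.maximum(concentration * np.asarray(mean_comp, dtype=float), 1e-12)
    p = rng.dirichlet(alpha)
    return rng.multinomial(n, p)


def _truncated_lognormal(rng: np.random.Generator, log_mean: float, log_sd: float,
                         lower: int, size: int) -> np.ndarray:
    out = np.empty(size, dtype=np.int64)
    filled = 0
    while filled < size:
        draw = rng.lognormal(log_mean, log_sd, size=size - filled)
        ok = draw >= lower
        k = int(ok.sum())
        out[filled:filled + k] = np.round(draw[ok]).astype(np.int64)
        filled += k
    return out


def generate_counts(params: SimulationParams) -> tuple[CountTable, list[EffectSpec]]:
    """Draw an OTU count table under the planted-effect model.

    For each sample: draw a library size from the truncated log-normal
    law, multiply the base composition by ``2**log2_fold_change`` for
    every effect applying to the sample's design cell, renormalize, draw
    a Dirichlet composition at the given concentration, then a
    multinomial count vector. Returns the table and the applied effects.
    """
    design = params.design
    rng = np.random.default_rng(np.random.SeedSequence([int(params.seed), 17]))
    comp = expected_composition(params).to_numpy()
    n_samples = len(design)
    libs = _truncated_lognormal(rng, params.library_log_mean, params.library_log_sd,
                                params.min_depth, n_samples)
    counts = np.empty((params.n_otus, n_samples), dtype=np.int64)
    for j in range(n_samples):
        counts[:, j] = dirichlet_multinomial(rng, comp[:, j], params.concentration,
                                             int(libs[j]))
    table = CountTable(_otu_ids(params.n_otus), list(design["sample_id"]), counts)
    return table, list(params.effects)


def generate_weights(design: pd.DataFrame,
                     base_adg_by_cell: Mapping[tuple, float] | float,
                     noise_sd: float = 30.0,
                     ages: Sequence[int] = (32, 39, 46, 53, 60),
                     weaning_weight_g: float = 700.0,
                     seed: int | None = 0) -> pd.DataFrame:
    """Attach weekly body weights to a design table.

    Weight at age ``a`` is ``weaning_weight + adg * (a - ages[0]) + noise``
    with the cell's average daily gain ``adg`` taken from
    ``base_adg_by_cell`` (keyed by (farm, batch, antibiotic, feeding),
    by (farm, feeding), or a single scalar for all cells).
    """
    ages = list(ages)
    if any(b <= a for a, b in zip(ages, ages[1:])) or len(set(ages)) != len(ages):
        raise ParameterError("ages must be strictly increasing")
    rng = np.random.default_rng(seed)
    design = validate_metadata(design)
    out = design.copy()

    def adg_for(row: pd.Series) -> float:
        if np.isscalar(base_adg_by_cell):
            return float(base_adg_by_cell)  # type: ignore[arg-type]
        cell4 = (row["farm"], row["batch"], row["antibiotic"], row["feeding"])
        cell2 = (row["farm"], row["feeding"])
        mapping = base_adg_by_cell  # type: ignore[assignment]
        if cell4 in mapping:
            return float(mapping[cell4])
        if cell2 in mapping:
            return float(mapping[cell2])
        raise ParameterError(f"no average daily gain given for cell {cell4}")

    adg = out.apply(adg_for, axis=1).to_numpy()
    for age in ages:
        noise = rng.normal(0.0, noise_sd, size=len(out)) if noise_sd > 0 else 0.0
        out[f"weight_{age}"] = weaning_weight_g + adg * (age - ages[0]) + noise
    return out


def two_farm_design(n_per_farm: int = 60) -> pd.DataFrame:
    """A minimal two-class design: one farm-A cell vs one farm-B cell.

    Used for two-class classification experiments where farm is the
    discriminant factor (batch 1 / batch 5, antibiotic feed, ad libitum).
    """
    rows = [("A", 1, "with", "AL")] * n_per_farm + [("B", 5, "with", "AL")] * n_per_farm
    meta = pd.DataFrame(rows, columns=["farm", "batch", "antibiotic", "feeding"])
    meta.insert(0, "sample_id", [f"S{i + 1:03d}" for i in range(len(meta))])
    return validate_metadata(meta)
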