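"""Seeded synthetic data with planted structure for every pipeline stage.

The generator emulates a high-pressure aquarium experiment on a
chemosynthetic symbiosis: worms are incubated under treatments that are
replete or limiting in sulfide, oxygen, nitrate and hydrogen; symbiont
gene expression is driven by latent module activities that respond to
those substrate states; and 13C-labelled inorganic carbon incorporation
is read out as tissue delta13C.

Counts are negative binomial with a gene-shared dispersion:

    counts_gs ~ NB(mu_gs, phi),
    log mu_gs = baseline_g + loading_g * ME_m(s) + log(libsize_s / mean libsize),
    ME_m(s)   = sum_c effect[m, c] * state_c(s) (centred) + N(0, me_noise_sd).

Genes outside modules have loading 0 (independent noise).  Two designated
"pathway" seed sets (a CBB-like and an rTCA-like set) are the
highest-loading members of two distinct modules, so their first-neighbour
sets in a recovered network are disjoint by construction.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tracer

SUBSTRATES = ("sulfide", "oxygen", "nitrate", "hydrogen")
STATES = ("replete", "limiting", "absent")

#: Treatment layout: ten aquarium conditions spanning replete, single-substrate
#: limitation and a no-amendment control, three worm replicates each.
DEFAULT_TREATMENTS: dict[str, dict[str, str]] = {
    "replete_a": {"sulfide": "replete", "oxygen": "replete", "nitrate": "replete", "hydrogen": "absent"},
    "replete_b": {"sulfide": "replete", "oxygen": "replete", "nitrate": "absent", "hydrogen": "absent"},
    "replete_h2": {"sulfide": "replete", "oxygen": "replete", "nitrate": "replete", "hydrogen": "replete"},
    "sulfide_limiting": {"sulfide": "limiting", "oxygen": "replete", "nitrate": "replete", "hydrogen": "absent"},
    "no_sulfide": {"sulfide": "absent", "oxygen": "replete", "nitrate": "replete", "hydrogen": "absent"},
    "oxygen_limiting": {"sulfide": "replete", "oxygen": "limiting", "nitrate": "replete", "hydrogen": "absent"},
    "no_oxygen": {"sulfide": "replete", "oxygen": "absent", "nitrate": "replete", "hydrogen": "absent"},
    "nitrate_limiting": {"sulfide": "replete", "oxygen": "replete", "nitrate": "limiting", "hydrogen": "absent"},
    "h2_low_sulfide": {"sulfide": "limiting", "oxygen": "replete", "nitrate": "replete", "hydrogen": "replete"},
    "control": {"sulfide": "absent", "oxygen": "absent", "nitrate": "absent", "hydrogen": "absent"},
}

#: Module -> condition log-scale effects. Module 0 tracks sulfide repletion
#: (CBB-like host module), module 4 responds to sulfide limitation with the
#: opposite sign (rTCA-like), modules 1-3 track oxygen / nitrate / hydrogen.
DEFAULT_EFFECTS: tuple[dict[str, float], ...] = (
    {"sulfide": 2.0},
    {"oxygen": 2.0},
    {"nitrate": 2.0},
    {"hydrogen": 2.0},
    {"sulfide": -2.0},
)


@dataclass
class SimulationConfig:
    """Knobs of the synthetic experiment; defaults are the study conditions."""

    n_genes: int = 1000
    module_sizes: tuple[int, ...] = (100, 100, 100, 100, 100)
    condition_layout: dict[str, dict[str, str]] = field(
        default_factory=lambda: dict(DEFAULT_TREATMENTS)
    )
    n_replicates: int = 3
    effect_sizes: tuple[dict[str, float], ...] = DEFAULT_EFFECTS
    me_noise_sd: float = 0.3
    loading_range: tuple[float, float] = (0.5, 1.0)
    nb_dispersion: float = 0.05
    baseline_logmean_range: tuple[float, float] = (2.5, 6.5)
    libsize_range: tuple[float, float] = (8e5, 1.2e6)
    seed_set_size: int = 10
    seed_set_modules: tuple[int, int] = (0, 4)
    rng_seed: int = 1

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_samples(self) -> int:
        return len(self.condition_layout) * self.n_replicates

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be > 0")
        if self.libsize_range[0] <= 0:
            raise ValueError("library sizes must be > 0")
        if len(self.effect_sizes) != self.n_modules:
            raise ValueError("one effect dict per module required")
        if self.seed_set_size > 0:
            if len(set(self.seed_set_modules)) != 2:
                raise ValueError("seed sets must live in two distinct modules")
            for m in self.seed_set_modules:
                if not 0 <= m < self.n_modules:
                    raise ValueError(f"seed-set module {m} out of range")
                if self.seed_set_size > self.module_sizes[m]:
                    raise ValueError("seed set larger than its module")
        for trt, states in self.condition_layout.items():
            for sub, state in states.items():
                if sub not in SUBSTRATES:
                    raise ValueError(f"treatment {trt!r}: unknown substrate {sub!r}")
                if state not in STATES:
                    raise ValueError(
                        f"treatment {trt!r}: substrate {sub!r} has state {state!r}; "
                        f"allowed states are {STATES}"
                    )


def _gene_ids(n: int) -> list[str]:
    return [f"g{i:04d}" for i in range(n)]


@dataclass
class GroundTruth:
    """Planted structure behind one simulated count matrix."""

    gene_module: dict[str, int]          # -1 = background noise gene
    loadings: dict[str, float]
    module_effects: list[dict[str, float]]
    module_me_by_treatment: dict[str, list[float]]  # treatment -> centred ME per module
    seed_sets: dict[str, list[str]]      # "CBB-like"/"rTCA-like" -> gene ids
    true_rates: dict[str, float] = field(default_factory=dict)

    def members(self, module: int) -> list[str]:
        return [g for g, m in self.gene_module.items() if m == module]

    def true_neighbors(self, seed_name: str) -> set[str]:
        """Module co-members of a seed set, excluding the seeds themselves."""
        seeds = set(self.seed_sets[seed_name])
        module = {self.gene_module[g] for g in seeds}.pop()
        return set(self.members(module)) - seeds

    def true_log2fc(self, gene: str, treatment_a: str, treatment_b: str) -> float:
        """Expected log2 fold change of a gene between two treatments."""
        m = self.gene_module[gene]
        if m < 0:
            return 0.0
        d = (
            self.module_me_by_treatment[treatment_a][m]
            - self.module_me_by_treatment[treatment_b][m]
        )
        return self.loadings[gene] * d / np.log(2.0)

    def condition_responsive_genes(
        self, condition: str, min_abs_effect: float = 0.5
    ) -> set[str]:
        """Genes in modules whose eigengene carries a condition effect."""
        out: set[str] = set()
        for m, eff in enumerate(self.module_effects):
            if abs(eff.get(condition, 0.0)) >= min_abs_effect:
                out.update(self.members(m))
        return out

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "GroundTruth":
        d = json.loads(text)
        d["module_effects"] = [dict(e) for e in d["module_effects"]]
        return cls(**d)


def simulate_design(config: SimulationConfig) -> pd.DataFrame:
    """Sample metadata table: one row per worm per treatment.

    Columns: sample, worm, treatment, cruise_year, and one state column per
    substrate.  Deterministic given the config (IDs are a pure function of
    the layout).
    """
    config.validate()
    rows = []
    worm_counter = 0
    for trt, states in config.condition_layout.items():
        for rep in range(config.n_replicates):
            worm_counter += 1
            row = {
                "sample": f"{trt}_w{rep + 1}",
                "worm": f"worm{worm_counter:03d}",
                "treatment": trt,
                "cruise_year": 2014 if rep % 2 == 0 else 2016,
            }
            for sub in SUBSTRATES:
                row[sub] = states.get(sub, "absent")
            rows.append(row)
    cols = ["sample", "worm", "treatment", "cruise_year", *SUBSTRATES]
    return pd.DataFrame(rows, columns=cols)


def _binary_state(state: str) -> float:
    return 1.0 if state == "replete" else 0.0


def _deterministic_me(config: SimulationConfig) -> dict[str, list[float]]:
    """Centred deterministic eigengene value per treatment per module."""
    treatments = list(config.condition_layout)
    raw = np.zeros((len(treatments), config.n_modules))
    for ti, trt in enumerate(treatments):
        states = config.condition_layout[trt]
        for m, eff in enumerate(config.effect_sizes):
            raw[ti, m] = sum(
                coef * _binary_state(states.get(sub, "absent")) for sub, coef in eff.items()
            )
    raw -= raw.mean(axis=0, keepdims=True)
    return {trt: raw[ti].tolist() for ti, trt in enumerate(treatments)}


def simulate_module_counts(
    config: SimulationConfig, design: pd.DataFrame
) -> tuple[pd.DataFrame, GroundTruth]:
    """Negative-binomial count matrix (genes x samples) plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    genes = _gene_ids(config.n_genes)
    samples = design["sample"].tolist()
    n_s = len(samples)

    # gene -> module assignment: modules occupy the first blocks, rest is noise
    gene_module = np.full(config.n_genes, -1, dtype=int)
    pos = 0
    for m, size in enumerate(config.module_sizes):
        gene_module[pos : pos + size] = m
        pos += size

    lo, hi = config.loading_range
    loadings = np.where(gene_module >= 0, rng.uniform(lo, hi, config.n_genes), 0.0)

    # seed sets: force the highest loading onto the first genes of their modules
    seed_sets: dict[str, list[str]] = {}
    seed_modules = config.seed_set_modules if config.seed_set_size > 0 else ()
    for name, m in zip(("CBB-like", "rTCA-like"), seed_modules):
        members = np.flatnonzero(gene_module == m)
        chosen = members[: config.seed_set_size]
        loadings[chosen] = hi
        seed_sets[name] = [genes[i] for i in chosen]

    me_det = _deterministic_me(config)
    me = np.zeros((config.n_modules, n_s))
    for si, trt in enumerate(design["treatment"]):
        me[:, si] = me_det[trt]
    me += rng.normal(0.0, config.me_noise_sd, size=me.shape)

    baseline = rng.uniform(*config.baseline_logmean_range, size=config.n_genes)
    libsize = rng.uniform(*config.libsize_range, size=n_s)
    offset = np.log(libsize / libsize.mean()) if n_s else np.zeros(0)

    log_mu = baseline[:, None] + offset[None, :]
    for m in range(config.n_modules):
        in_m = gene_module == m
        log_mu[in_m] += loadings[in_m, None] * me[m][None, :]
    mu = np.exp(log_mu)

    # NB via gamma-Poisson mixture; dispersion phi -> Var = mu + phi mu^2
    phi = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / phi, scale=mu * phi)
    counts = rng.poisson(lam).astype(np.int64)

    matrix = pd.DataFrame(counts, index=genes, columns=samples)
    truth = GroundTruth(
        gene_module={g: int(m) for g, m in zip(genes, gene_module)},
        loadings={g: float(l) for g, l in zip(genes, loadings)},
        module_effects=[dict(e) for e in config.effect_sizes],
        module_me_by_treatment=me_det,
        seed_sets=seed_sets,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# isotope and flow-through chemistry generators (algebraic inverses of the
# rate formulas in ventnet.tracer)
# ---------------------------------------------------------------------------

def simulate_isotope_records(
    true_rates: dict[str, float],
    label_atom_pct_water: float = 2.64,
    hours: float = 48.0,
    dw_ww_ratio: float = 0.15,
    noise_sd_delta: float = 0.0,
    delta13c_nat: float = -20.0,
    n_nat_refs: int = 3,
    tissue: str = "trophosome",
    r_standard: float = tracer.R_VPDB,
    seed: int = 0,
) -> tuple[list[tracer.IsotopeRecord], dict[str, float]]:
    """Tissue delta13C records whose noiseless inversion recovers ``true_rates``.

    ``true_rates`` are dry-weight incorporation rates (umol g-1 h-1, the
    DryC_inc scale).  Noise is per-mille Gaussian on the measured deltas.
    Returns the records and the rates actually planted (= input, echoed for
    GroundTruth bookkeeping).
    """
    rng = np.random.default_rng(seed)
    a_nat = tracer.atom_percent(tracer.ratio_from_delta(delta13c_nat, r_standard))
    if label_atom_pct_water <= a_nat:
        raise ValueError(
            f"label_atom_pct_water ({label_atom_pct_water}) must exceed the natural "
            f"abundance atom percent ({a_nat:.4f})"
        )
    nat_refs = tuple(
        float(delta13c_nat + rng.normal(0.0, noise_sd_delta)) for _ in range(n_nat_refs)
    )
    records = []
    for worm, rate in true_rates.items():
        if rate < 0:
            raise ValueError(f"true rate for {worm} is negative")
        frac = rate * tracer.MW_13C * hours / 1000.0
        if frac > 1.0:
            raise ValueError(
                f"rate {rate} over {hours} h implies >100% label incorporation"
            )
        a_lab = a_nat + frac * (label_atom_pct_water - a_nat)
        delta_lab = tracer.delta13c(tracer.ratio_from_atom_percent(a_lab), r_standard)
        delta_lab += rng.normal(0.0, noise_sd_delta)
        records.append(
            tracer.IsotopeRecord(
                worm_id=worm,
                tissue=tissue,
                delta13c_lab=float(delta_lab),
                delta13c_nat_refs=nat_refs,
                a_pct_water=label_atom_pct_water,
                dry_weight_g=float(rng.uniform(0.1, 1.0)),
                hours=hours,
                dw_ww_ratio=dw_ww_ratio,
                r_standard=r_standard,
            )
        )
    return records, dict(true_rates)


def simulate_uptake_series(
    c_in: float,
    consumption: float,
    biomass: float,
    flow: float,
    n_timepoints: int = 10,
    noise_sd: float = 0.0,
    substrate: str = "H2S",
    seed: int = 0,
) -> list[tracer.UptakeRecord]:
    """Inlet/outlet concentration series consistent with a planted uptake rate.

    ``consumption`` is umol g-1 h-1; the implied outlet concentration is
    c_out = c_in - consumption * biomass / flow, rejected if negative.
    Measurement noise (sd in umol/l) is added independently to both measured
    concentrations.
    """
    if flow <= 0 or biomass <= 0:
        raise ValueError("flow and biomass must be > 0")
    c_out = c_in - consumption * biomass / flow
    if c_out < 0:
        raise ValueError(
            f"consumption {consumption} umol/g/h implies negative outlet "
            f"concentration ({c_out:.3f} umol/l)"
        )
    rng = np.random.default_rng(seed)
    records = []
    for t in range(n_timepoints):
        records.append(
            tracer.UptakeRecord(
                substrate=substrate,
                c_in=float(c_in + rng.normal(0.0, noise_sd)),
                c_out=float(c_out + rng.normal(0.0, noise_sd)),
                flow_l_per_h=flow,
                biomass_g=biomass,
                timestamp=float(t),
            )
        )
    return records
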