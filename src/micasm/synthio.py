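"""Synthetic serial-transfer microcosm experiments with ground truth.

Emulates a 35-day press-disturbance design: five treatment arms (a
micropollutant-free control, two single compounds, two mixtures) x 3
replicate bottles x 7 five-day batches, with 10% of each bottle
transferred into fresh medium and a fresh micropollutant spike at every
batch boundary.  Chemistry is observed at days 0/2/5 of each batch and
community composition is observed once per batch as a multinomial
sequencing draw from the latent cell pool.

The latent dynamics are deliberately simple:

* a shared regional species pool; each bottle activates a random subset
  of it at inoculation with lognormal weights (stochastic resuscitation
  from the seed bank), which is what makes early-batch composition
  genuinely random with respect to taxon identity;
* discrete-time per-day exponential growth, with a per-OTU rate modified
  by a subsidy gain (degraders consuming carbon-source compounds) and a
  stress penalty scaled by ``1 - tolerance`` (antimicrobial-like
  compounds), both proportional to the current dissolved concentration;
* demographic drift via daily multinomial resampling of the pool at a
  fixed effective size, plus a binomial bottleneck at each transfer;
* first-order chemical decay driven by the responding biomass fraction
  (degrader biomass for subsidy compounds, tolerance-weighted biomass
  for stress compounds), with total biomass following a discrete
  logistic recovery after each dilution.

The tolerance trait evolves by Brownian motion on the simulated
phylogeny, so selection for tolerant taxa is phylogenetically clustered
and detectable by nearest-taxon null models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import CommunityTable, validate_chem

#: compound -> response class ("subsidy": used as a carbon source;
#: "stress": growth-inhibiting).  Analog compounds mirror their parents.
COMPOUND_ROLES = {"BPA": "subsidy", "BPS": "subsidy",
                  "TCS": "stress", "TCC": "stress"}


@dataclass(frozen=True)
class Treatment:
    """One experimental arm: a name and its spiked compounds (ug/L)."""

    name: str
    compounds: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.compounds.values()):
            raise ValidationError(f"negative concentration in arm {self.name!r}")


def default_treatments() -> list[Treatment]:
    """The five arms of the reference design (concentrations in ug/L)."""
    return [
        Treatment("Control", {}),
        Treatment("BPA", {"BPA": 1.0}),
        Treatment("TCS", {"TCS": 1.0}),
        Treatment("MI", {"BPA": 1.0, "TCS": 1.0}),
        Treatment("MII", {"BPA": 1.0, "BPS": 0.1, "TCS": 1.0, "TCC": 0.1}),
    ]


@dataclass
class SimConfig:
    """Parameters of one synthetic experiment.

    Volumes are in mL, concentrations in ug/L, rates per day.  The
    transfer fraction must equal inoculum_volume / total_volume.
    ``selection_strength = 0`` switches the generator to its neutral
    regime (pure drift); positive values scale both the subsidy gain and
    the stress penalty.
    """

    n_otus: int = 150
    n_batches: int = 7
    batch_days: int = 5
    treatments: list[Treatment] = field(default_factory=default_treatments)
    n_replicates: int = 3
    transfer_fraction: float = 0.10
    inoculum_volume: float = 60.0
    total_volume: float = 600.0
    sequencing_depth: int = 36_000
    selection_strength: float = 1.0
    trait_bm_sigma: float = 1.0
    degrader_fraction: float = 0.2
    decay_coupling: float = 3.0
    seed: int = 0
    # generator-specific knobs (see docs/methods.md for rationale)
    stress_decay_ratio: float = 0.1
    base_growth: float = 1.0
    subsidy_gain: float = 0.05
    stress_penalty: float = 1.0
    effective_size: int = 10000
    activation_fraction: float = 0.35
    activation_concentration: float = 1.0
    activation_sigma: float = 0.2
    pool_evenness: float = 1.0
    reference_concentration: float = 1.0
    abiotic: bool = False
    preexposed: bool = False
    preexposure_strength: float = 1.0

    def __post_init__(self) -> None:
        if self.n_otus < 2:
            raise ValidationError("n_otus must be >= 2")
        if self.inoculum_volume <= 0 or self.total_volume <= 0:
            raise ValidationError("volumes must be positive")
        if abs(self.transfer_fraction
               - self.inoculum_volume / self.total_volume) > 1e-9:
            raise ValidationError(
                "transfer_fraction must equal inoculum_volume / total_volume")
        if not 0 < self.transfer_fraction < 1:
            raise ValidationError("transfer_fraction must lie in (0, 1)")
        if self.sequencing_depth < 1:
            raise ValidationError("sequencing_depth must be >= 1")
        if self.selection_strength < 0:
            raise ValidationError("selection_strength must be >= 0")
        if not 0 <= self.degrader_fraction <= 1:
            raise ValidationError("degrader_fraction must lie in [0, 1]")
        names = [t.name for t in self.treatments]
        if len(names) != len(set(names)):
            raise ValidationError("treatment names must be unique")

    @property
    def regime(self) -> str:
        return "neutral" if self.selection_strength == 0 else "selection"


@dataclass
class SimTruth:
    """Ground truth behind one simulated experiment."""

    tolerance: pd.Series           # per OTU, in (0, 1)
    degrader: pd.Series            # per OTU, bool
    latent: pd.DataFrame           # (microcosm, batch, day) x OTU compositions
    regime: str                    # "neutral" | "selection"
    chem_params: dict[str, float]  # compound -> decay coefficient (per day)

    def to_json(self, path) -> None:
        payload = {
            "regime": self.regime,
            "chem_params": self.chem_params,
            "tolerance": {k: float(v) for k, v in self.tolerance.items()},
            "degrader": {k: bool(v) for k, v in self.degrader.items()},
            "otu_order": list(self.latent.columns),
            "latent": {
                f"{m}|{b}|{d}": [float(x) for x in row]
                for (m, b, d), row in self.latent.iterrows()
            },
        }
        Path(path).write_text(json.dumps(payload, sort_keys=True))


# -- phylogeny and traits -------------------------------------------------

def simulate_tree(n_otus: int, seed: int) -> dendropy.Tree:
    """Random coalescent tree over ``n_otus`` tips.

    Lineages are merged pairwise, uniformly at random, with exponential
    waiting times at the standard coalescent rate k(k-1)/2, yielding a
    rooted binary ultrametric tree with strictly positive branch lengths.
    Deterministic for a given seed (byte-identical Newick).
    """
    if n_otus < 2:
        raise ValidationError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    names = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    nodes = [(name, 0.0) for name in names]  # (newick fragment, height)
    t = 0.0
    while len(nodes) > 1:
        k = len(nodes)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = sorted(rng.choice(k, size=2, replace=False))
        (nw_j, h_j) = nodes.pop(j)
        (nw_i, h_i) = nodes.pop(i)
        frag = f"({nw_i}:{t - h_i:.10f},{nw_j}:{t - h_j:.10f})"
        nodes.append((frag, t))
    newick = nodes[0][0] + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


def _brownian_tip_values(tree: dendropy.Tree, sigma: float,
                         rng: np.random.Generator) -> pd.Series:
    """Brownian motion along branches; root value 0."""
    values: dict[int, float] = {}
    out: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        if parent is None:
            values[id(node)] = 0.0
        else:
            edge = node.edge.length or 0.0
            step = rng.normal(0.0, sigma * np.sqrt(edge)) if sigma > 0 else 0.0
            values[id(node)] = values[id(parent)] + step
        if node.is_leaf():
            out[node.taxon.label] = values[id(node)]
    return pd.Series(out).sort_index()


def simulate_traits(tree: dendropy.Tree, trait_bm_sigma: float,
                    degrader_fraction: float, seed: int
                    ) -> tuple[pd.Series, pd.Series]:
    """Per-OTU stress tolerance and degrader status.

    Tolerance is a logistic squash of a Brownian-motion trait on the tree
    (root value 0 -> tolerance 0.5), so closely related OTUs have similar
    tolerances.  Degrader status is an independent Bernoulli draw at rate
    ``degrader_fraction``.
    """
    if not 0 <= degrader_fraction <= 1:
        raise ValidationError("degrader_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    raw = _brownian_tip_values(tree, trait_bm_sigma, rng)
    tolerance = pd.Series(1.0 / (1.0 + np.exp(-raw)), index=raw.index,
                          name="tolerance")
    degrader = pd.Series(rng.random(len(raw)) < degrader_fraction,
                         index=raw.index, name="degrader")
    return tolerance, degrader


def simulate_copy_numbers(tree: dendropy.Tree, seed: int,
                          autocorrelation: bool = True,
                          unassigned_fraction: float = 0.0) -> pd.Series:
    """Integer 16S copy numbers in [1, 15] per OTU (rrnDB-style map).

    With ``autocorrelation`` the integers follow the rank order of a
    Brownian trait on the tree, so relatives share similar copy numbers;
    otherwise they are i.i.d. uniform.  ``unassigned_fraction`` of OTUs
    is dropped from the map to exercise missing-data handling downstream.
    """
    if not 0 <= unassigned_fraction <= 1:
        raise ValidationError("unassigned_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    n = len(labels)
    if autocorrelation:
        raw = _brownian_tip_values(tree, 1.0, rng).loc[labels]
        ranks = raw.rank(method="first").to_numpy() - 1.0
        values = 1 + np.floor(15.0 * ranks / n).astype(int)
    else:
        values = rng.integers(1, 16, size=n)
    values = np.clip(values, 1, 15)
    keep = rng.random(n) >= unassigned_fraction
    return pd.Series(values, index=labels, name="copy_number")[keep].astype(int)


# -- latent dynamics ------------------------------------------------------

def transfer_thinning(cells: np.ndarray, fraction: float,
                      rng: np.random.Generator) -> np.ndarray:
    """Serial transfer: independent binomial survival of each cell.

    Implements the 10% dilution of a transfer step; each of the
    ``cells[i]`` individuals of OTU i enters the next bottle with
    probability ``fraction``.
    """
    if not 0 < fraction < 1:
        raise ValidationError("transfer fraction must lie in (0, 1)")
    thinned = rng.binomial(cells, fraction)
    if thinned.sum() == 0 and cells.sum() > 0:
        # re-inoculation guard: a transfer never sterilizes the line
        thinned[int(np.argmax(cells))] = 1
    return thinned


def simulate_experiment(config: SimConfig
                        ) -> tuple[CommunityTable, pd.DataFrame, SimTruth]:
    """Run one full serial-transfer experiment.

    Returns the sequenced community table (one sample per treatment x
    replicate x batch), the chemistry time series (days 0/2/5 of every
    batch for every spiked compound) and the generator's ground truth.
    """
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_traits, s_pool, s_dyn = [int(c.generate_state(1)[0] % (2**31))
                                       for c in ss.spawn(4)]
    tree = simulate_tree(config.n_otus, s_tree)
    tolerance, degrader = simulate_traits(
        tree, config.trait_bm_sigma, config.degrader_fraction, s_traits)
    otus = list(tolerance.index)
    n = len(otus)
    tol = tolerance.to_numpy()
    deg = degrader.to_numpy().astype(float)

    pool_rng = np.random.default_rng(s_pool)
    regional = pool_rng.dirichlet(np.full(n, config.pool_evenness))
    # per-taxon resuscitation propensity: taxa differ persistently in how
    # readily they wake from the seed bank, so sample occupancy carries
    # real information about activation probability
    mu, c = config.activation_fraction, config.activation_concentration
    propensity = pool_rng.beta(mu * c, (1.0 - mu) * c, size=n)
    dyn_rng = np.random.default_rng(s_dyn)

    chem_params = {}
    for trt in config.treatments:
        for comp in trt.compounds:
            role = COMPOUND_ROLES.get(comp, "subsidy")
            k = config.decay_coupling
            chem_params[comp] = k if role == "subsidy" else k * config.stress_decay_ratio

    counts_rows, meta_rows, chem_rows, latent_rows = [], [], [], []
    ref = config.reference_concentration
    n_eff = config.effective_size

    for trt in config.treatments:
        for rep in range(1, config.n_replicates + 1):
            microcosm = f"{trt.name}_r{rep}"
            # seed-bank activation lottery at inoculation
            active = dyn_rng.random(n) < propensity
            if not active.any():
                active[dyn_rng.integers(n)] = True
            w = regional * active * np.exp(
                dyn_rng.normal(0.0, config.activation_sigma, size=n))
            if config.preexposed:
                w = w * np.exp(config.preexposure_strength * (deg + tol))
            comp0 = w / w.sum()
            cells = dyn_rng.multinomial(n_eff, comp0)
            if config.abiotic:
                cells = np.zeros(n, dtype=np.int64)
            biomass = config.transfer_fraction

            for b in range(1, config.n_batches + 1):
                batch = f"B{b}"
                conc = dict(trt.compounds)  # fresh spike with the new medium
                for compound, c0 in conc.items():
                    chem_rows.append((microcosm, trt.name, rep, batch,
                                      compound, 0, c0))
                total = cells.sum()
                latent_rows.append(((microcosm, batch, 0),
                                    cells / total if total else cells * 0.0))
                for day in range(1, config.batch_days + 1):
                    if not config.abiotic:
                        subsidy_lvl = sum(c / ref for comp_, c in conc.items()
                                          if COMPOUND_ROLES.get(comp_) == "subsidy")
                        stress_lvl = sum(c / ref for comp_, c in conc.items()
                                         if COMPOUND_ROLES.get(comp_) == "stress")
                        rate = config.base_growth + config.selection_strength * (
                            config.subsidy_gain * deg * subsidy_lvl
                            - config.stress_penalty * (1.0 - tol) * stress_lvl)
                        weights = cells * np.exp(rate - config.base_growth)
                        cells = dyn_rng.multinomial(n_eff,
                                                    weights / weights.sum())
                        biomass = biomass + config.base_growth * biomass * (1 - biomass)
                        frac = cells / n_eff
                        for compound in conc:
                            role = COMPOUND_ROLES.get(compound, "subsidy")
                            resp = biomass * (float(frac @ deg) if role == "subsidy"
                                              else float(frac @ tol))
                            conc[compound] *= np.exp(-chem_params[compound] * resp)
                    if day in (2, config.batch_days):
                        for compound, c in conc.items():
                            chem_rows.append((microcosm, trt.name, rep, batch,
                                              compound, day, c))
                # sequencing sample, taken prior to the next inoculation
                total = cells.sum()
                comp_now = cells / total if total else np.zeros(n)
                latent_rows.append(((microcosm, batch, config.batch_days), comp_now))
                reads = (dyn_rng.multinomial(config.sequencing_depth, comp_now)
                         if total else np.zeros(n, dtype=np.int64))
                sample_id = f"{trt.name}_r{rep}_{batch}"
                counts_rows.append(pd.Series(reads, index=otus, name=sample_id))
                meta_rows.append((sample_id, trt.name, batch, rep,
                                  config.batch_days * b))
                if b < config.n_batches and not config.abiotic:
                    cells = transfer_thinning(cells, config.transfer_fraction,
                                              dyn_rng)
                    biomass *= config.transfer_fraction

    counts = pd.DataFrame(counts_rows)
    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "treatment",
                                                "batch", "replicate", "day"]
                            ).set_index("sample_id")
    table = CommunityTable(counts, metadata)
    chem = validate_chem(pd.DataFrame(
        chem_rows, columns=["microcosm_id", "treatment", "replicate", "batch",
                            "compound", "day", "concentration_ugL"]))
    latent = pd.DataFrame(
        [row for _, row in latent_rows],
        index=pd.MultiIndex.from_tuples([k for k, _ in latent_rows],
                                        names=["microcosm", "batch", "day"]),
        columns=otus)
    truth = SimTruth(tolerance=tolerance, degrader=degrader, latent=latent,
                     regime=config.regime, chem_params=chem_params)
    return table, chem, truth


# -- auxiliary generator for dissimilarity-overlap behavior ---------------

def simulate_universal_samples(n_samples: int = 21, n_otus: int = 100,
                               depth: int = 10_000, kappa_min: float = 20.0,
                               kappa_max: float = 2000.0, seed: int = 0
                               ) -> CommunityTable:
    """Samples sharing one underlying composition with graded noise.

    Every sample is a multinomial draw around a single latent composition,
    perturbed by a Dirichlet whose concentration varies per sample across
    ``[kappa_min, kappa_max]``.  Low-noise sample pairs share more taxon
    mass (high overlap) and diverge less (low dissimilarity), so the
    overlap-dissimilarity relation is negative by construction -- the
    shared-dynamics reference case for DOC analysis.
    """
    rng = np.random.default_rng(seed)
    base = rng.dirichlet(np.ones(n_otus))
    otus = [f"OTU_{i + 1:04d}" for i in range(n_otus)]
    rows, meta = [], []
    kappas = np.exp(rng.uniform(np.log(kappa_min), np.log(kappa_max),
                                size=n_samples))
    for i, kappa in enumerate(kappas):
        compo = rng.dirichlet(base * kappa + 1e-9)
        reads = rng.multinomial(depth, compo)
        sid = f"UNIV_s{i + 1:02d}"
        rows.append(pd.Series(reads, index=otus, name=sid))
        meta.append((sid, "UNIV", f"B{i % 7 + 1}", i // 7 + 1, 5 * (i % 7 + 1)))
    counts = pd.DataFrame(rows)
    metadata = pd.DataFrame(meta, columns=["sample_id", "treatment", "batch",
                                           "replicate", "day"]).set_index("sample_id")
    return CommunityTable(counts, metadata)
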