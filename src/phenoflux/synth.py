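"""Synthetic data generators with planted ground truth.

Every pipeline stage is testable without downloads:

* ``gen_pm_plate`` — a 96-well phenotype-microarray plate (plus its blank
  plate) with a known set of positive wells. Respiration traces are logistic
  curves over a linear abiotic dye drift with Gaussian noise — the simplest
  family matching observed sigmoid PM kinetics; a stand-in for, not a model
  of, tetrazolium dye chemistry. Well A1 is the negative-control (water)
  well, per Biolog plate convention.
* ``gen_toy_model`` — chain-structured metabolic models with an analytic
  answer sheet: the optimum is the sum over chains of each chain's tightest
  capacity, shadow prices are 0/1 by position relative to the binding
  constraint, and planted no-production metabolites are root gaps by
  construction.
* ``gen_blast_hits`` — BLAST tabular rows with a known pass/fail split
  around an E-value cutoff.
* ``synthetic_base_model`` — a SYNTHETIC stand-in base network reproducing
  the printed size of the iRC1080 model (2,191 reactions, 1,706 metabolites,
  1,086 genes): a small functional core (light/dark-switchable biomass
  production, amino-acid supply, pre-seeded d-alanine / d-serine /
  ethanolamine carriers) padded with a deterministic reversible filler
  network. It reproduces the published model's *size*, not its content.

All generators are pure functions of their spec (seed included).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import Metabolite, Model, Reaction
from .pm_kinetics import ROWS, Role, WellTimeSeries

__all__ = [
    "PlateSpec",
    "ToyModelSpec",
    "gen_pm_plate",
    "gen_toy_model",
    "gen_blast_hits",
    "synthetic_base_model",
]


# ---------------------------------------------------------------------------
# PM plates


@dataclass(frozen=True)
class PlateSpec:
    """Parameters of one synthetic PM plate.

    Amplitudes (OmniLog units) of planted positives sit far above the
    abiotic background; with the defaults the worst-case margin is
    ``min(amplitude) - drift * t_max ~ 140`` units against a noise sigma of
    2 — comfortably recoverable.
    """

    seed: int = 0
    plate_id: str = "PM01"
    n_positive: int = 10
    amplitude_range: tuple = (150.0, 250.0)
    steepness: float = 0.08  # 1/h
    midpoint_range: tuple = (40.0, 90.0)  # h
    noise_sigma: float = 2.0  # units
    abiotic_drift: float = 0.05  # units/h in every well incl. blanks
    t_max: float = 168.0  # h
    dt: float = 1.0  # h


def gen_pm_plate(spec: PlateSpec) -> tuple[list[WellTimeSeries], dict]:
    """Generate one plate (test wells + blank plate) and truth labels.

    Returns ``(wells, labels)`` where ``wells`` holds 96 assay traces (A1 is
    the negative control) plus 96 blank traces with matching well ids, and
    ``labels`` maps well_id -> planted-positive boolean for the test wells.
    """
    if spec.n_positive > 94:
        raise ValueError(
            f"n_positive={spec.n_positive} exceeds the 94 assay wells "
            "(96 minus control and blank)"
        )
    rng = np.random.default_rng(spec.seed)
    t = np.arange(0.0, spec.t_max + spec.dt / 2, spec.dt)
    well_ids = [f"{r}{c}" for r in ROWS for c in range(1, 13)]
    candidates = [w for w in well_ids if w != "A1"]
    positive_wells = set(
        rng.choice(candidates, size=spec.n_positive, replace=False)
    )

    wells: list[WellTimeSeries] = []
    labels: dict[str, bool] = {}
    for w in well_ids:
        drift = spec.abiotic_drift * t
        noise = rng.normal(0.0, spec.noise_sigma, size=t.shape)
        if w == "A1":
            signal = drift + noise
            wells.append(
                WellTimeSeries(spec.plate_id, w, "Negative Control",
                               Role.NEGATIVE_CONTROL, t, signal)
            )
            continue
        if w in positive_wells:
            amp = rng.uniform(*spec.amplitude_range)
            mid = rng.uniform(*spec.midpoint_range)
            logistic = amp / (1.0 + np.exp(-spec.steepness * (t - mid)))
        else:
            logistic = np.zeros_like(t)
        wells.append(
            WellTimeSeries(spec.plate_id, w, f"compound_{w}", Role.TEST, t,
                           logistic + drift + noise)
        )
        labels[w] = w in positive_wells
    # blank plate: abiotic signal only, one blank trace per well
    for w in well_ids:
        drift = spec.abiotic_drift * t
        noise = rng.normal(0.0, spec.noise_sigma, size=t.shape)
        wells.append(
            WellTimeSeries(spec.plate_id, w, f"blank_{w}", Role.BLANK, t,
                           drift + noise)
        )
    return wells, labels


# ---------------------------------------------------------------------------
# toy metabolic models


@dataclass(frozen=True)
class ToyModelSpec:
    seed: int = 0
    n_chains: int = 3
    chain_length_range: tuple = (2, 5)  # interior metabolites per chain
    uptake_range: tuple = (5.0, 15.0)
    planted_bottleneck: float | None = 4.0  # interior cap on chain 0
    planted_gaps: int = 0


def gen_toy_model(spec: ToyModelSpec) -> tuple[Model, dict]:
    """Build a chain network with an analytic answer sheet.

    Each chain takes up a source through a capped exchange and converts it,
    step by step, into a common biomass precursor ``prec[c]``; biomass drains
    the precursor and is the objective. Chain 0 optionally carries an
    interior bottleneck strictly tighter than its uptake, so its binding
    constraint sits mid-chain; the other chains bind at uptake. The answer
    sheet gives the optimum, the 0/1 shadow price of every chain metabolite
    and the planted root-gap list.
    """
    rng = np.random.default_rng(spec.seed)
    model = Model(id=f"toy_{spec.seed}")
    prec = Metabolite("prec[c]", name="biomass precursor")
    model.add_metabolite(prec)

    optimum = 0.0
    shadow: dict[str, float] = {"prec[c]": 1.0}
    for i in range(spec.n_chains):
        length = int(rng.integers(*spec.chain_length_range))
        # distinct uptake caps keep every binding constraint unique
        cap = float(np.round(rng.uniform(*spec.uptake_range), 3)) + i * 20.0
        mets = [Metabolite(f"m{i}_{k}[c]") for k in range(length)]
        for m in mets:
            model.add_metabolite(m)
        model.add_reaction(
            Reaction(
                id=f"EX_m{i}_0",
                stoichiometry={mets[0].id: -1},
                reversible=True,
                lower_bound=-cap,
                upper_bound=0.0,
                category="exchange",
            )
        )
        bottleneck_pos = None
        chain_flux = cap
        if (
            i == 0
            and spec.planted_bottleneck is not None
            and spec.planted_bottleneck < cap  # strictly tighter, else inert
        ):
            bottleneck_pos = length - 1  # the edge draining the last met
            chain_flux = spec.planted_bottleneck
        for k in range(length):
            target = mets[k + 1].id if k + 1 < length else "prec[c]"
            ub = 1000.0
            if bottleneck_pos is not None and k == bottleneck_pos:
                ub = spec.planted_bottleneck
            model.add_reaction(
                Reaction(
                    id=f"chain{i}_{k}",
                    stoichiometry={mets[k].id: -1, target: 1},
                    reversible=False,
                    upper_bound=ub,
                )
            )
        optimum += chain_flux
        for k, m in enumerate(mets):
            if bottleneck_pos is not None and k <= bottleneck_pos:
                # a free unit upstream of the bottleneck still cannot pass it
                shadow[m.id] = 0.0
            else:
                shadow[m.id] = 1.0

    model.add_reaction(
        Reaction(id="biomass", stoichiometry={"prec[c]": -1}, reversible=False)
    )
    model.objective = "biomass"

    gap_ids = []
    for g in range(spec.planted_gaps):
        gm = Metabolite(f"gap{g}[c]")
        model.add_metabolite(gm)
        model.add_reaction(
            Reaction(
                id=f"gapuse{g}",
                stoichiometry={gm.id: -1, "prec[c]": 1},
                reversible=False,
            )
        )
        gap_ids.append(gm.id)
        shadow[gm.id] = 1.0  # a free unit of the orphan feeds the precursor

    answer = {
        "optimum": optimum,
        "shadow_prices": shadow,
        "gaps": frozenset(gap_ids),
    }
    return model, answer


# ---------------------------------------------------------------------------
# BLAST evidence


def gen_blast_hits(
    seed: int, n_pass: int, n_fail: int, e_max: float = 0.005
) -> tuple[pd.DataFrame, pd.Series]:
    """Outfmt-6-style rows with exactly ``n_pass`` E-values below ``e_max``."""
    if e_max <= 0:
        raise ValueError("e_max must be positive to plant passing hits")
    rng = np.random.default_rng(seed)
    rows = []
    labels = []
    for i in range(n_pass + n_fail):
        passing = i < n_pass
        if passing:
            ev = e_max * 10.0 ** (-rng.uniform(1.0, 20.0))
        else:
            ev = e_max * 10.0 ** (rng.uniform(0.0, 3.0))
        rows.append(
            {
                "qseqid": f"compound{i}|1.1.1.{i + 1}",
                "sseqid": f"XP_{900000 + i}.1",
                "pident": float(np.round(rng.uniform(30, 99), 1)),
                "length": int(rng.integers(80, 500)),
                "mismatch": int(rng.integers(0, 50)),
                "gapopen": int(rng.integers(0, 5)),
                "qstart": 1, "qend": 100, "sstart": 1, "send": 100,
                "evalue": ev,
                "bitscore": float(np.round(rng.uniform(40, 400), 1)),
            }
        )
        labels.append(passing)
    order = rng.permutation(len(rows))
    df = pd.DataFrame([rows[i] for i in order])
    return df, pd.Series([labels[i] for i in order], name="planted_pass")


# ---------------------------------------------------------------------------
# synthetic base network (printed-size stand-in)

#: medium components with their maximal uptake rates (mmol/gDW/h); photon
#: and acetate are finite so the light/dark presets have distinct optima
_MEDIUM = {
    "photon": 60.0,
    "ac": 30.0,
    "nh4": 25.0,  # nitrogen-limited under light, so new N routes matter
    "pi": 1000.0,
    "so4": 1000.0,
    "h2o": 1000.0,
    "co2": 1000.0,
    "o2": 1000.0,
}

_BASE_REACTIONS = 2191
_BASE_METABOLITES = 1706
_BASE_GENES = 1086


def synthetic_base_model() -> Model:
    """Deterministic SYNTHETIC stand-in for a curated base network.

    Reproduces the printed iRC1080 model size — 2,191 reactions, 1,706
    metabolites, 1,086 genes — around a small functional core:

    * medium exchanges and passive transports for photons, acetate and
      inorganic nutrients,
    * carbon fixation from photons+CO2 (light) or acetate (dark) into a
      biomass precursor, ATP synthesis and biomass as the objective,
    * synthesis of the 20 l-amino acids,
    * pre-existing carriers for d-alanine, d-serine and ethanolamine
      (compounds whose uptake the expanded network re-uses),
    * a reversible filler network carrying the remaining metabolite,
      reaction and gene counts; filler is disconnected from biomass and
      gap-free by construction.

    The stand-in supports count arithmetic, expansion and gap-delta
    demonstrations; it does not reproduce the real network's root gaps or
    shadow prices.
    """
    from .model.construct import AMINO_ACIDS, COFACTORS

    model = Model(id="synthetic_base")

    def met(mid, **kw):
        if mid not in model.metabolites:
            model.add_metabolite(Metabolite(mid, **kw))

    for base, uptake in _MEDIUM.items():
        met(f"{base}[e]")
        met(f"{base}[c]")
        model.add_reaction(
            Reaction(
                id=f"EX_{base}_e",
                stoichiometry={f"{base}[e]": -1},
                reversible=True,
                lower_bound=-uptake,
                upper_bound=1000.0,
                category="exchange",
            )
        )
        model.add_reaction(
            Reaction(
                id=f"TRANS_{base}",
                stoichiometry={f"{base}[e]": -1, f"{base}[c]": 1},
                reversible=True,
                category="transport",
            )
        )

    met("fix[c]", name="fixed carbon")
    model.add_reaction(
        Reaction(
            id="PHOTOFIX",
            stoichiometry={"photon[c]": -1, "co2[c]": -1, "fix[c]": 1},
            reversible=False,
        )
    )
    model.add_reaction(
        Reaction(
            id="ACFIX",
            stoichiometry={"ac[c]": -1, "fix[c]": 1},
            reversible=False,
        )
    )
    name, formula, charge = COFACTORS["atp"]
    met("atp[c]", name=name, formula=formula, charge=charge)
    model.add_reaction(
        Reaction(
            id="ATPSYN",
            stoichiometry={"fix[c]": -1, "pi[c]": -1, "atp[c]": 1},
            reversible=False,
        )
    )
    model.add_reaction(
        Reaction(
            id="BIOMASS",
            name="biomass (dark/light)",
            stoichiometry={
                "fix[c]": -1, "nh4[c]": -0.5, "pi[c]": -0.1, "so4[c]": -0.05
            },
            reversible=False,
        )
    )
    model.objective = "BIOMASS"

    for code, (aa_id, aa_name, aa_formula) in sorted(AMINO_ACIDS.items()):
        met(f"{aa_id}[c]", name=aa_name, formula=aa_formula, charge=0)
        model.add_reaction(
            Reaction(
                id=f"AASYN_{aa_id}",
                stoichiometry={"fix[c]": -1, "nh4[c]": -1, f"{aa_id}[c]": 1},
                reversible=False,
            )
        )

    # pre-existing passive carriers (see module docstring)
    for base in ("ala__D", "ser__D", "etha"):
        met(f"{base}[e]", boundary=True)
        met(f"{base}[c]")
        model.add_reaction(
            Reaction(
                id=f"TRANS_{base}",
                stoichiometry={f"{base}[e]": -1, f"{base}[c]": 1},
                reversible=True,
                category="transport",
            )
        )

    # deterministic reversible filler to the printed counts
    n_fill_m = _BASE_METABOLITES - len(model.metabolites)
    n_fill_r = _BASE_REACTIONS - len(model.reactions)
    assert n_fill_m > 0 and n_fill_r >= max(n_fill_m, _BASE_GENES)
    for i in range(n_fill_m):
        model.add_metabolite(Metabolite(f"f{i:04d}[c]"))
    for j in range(n_fill_r):
        a = j % n_fill_m
        b = (j * 17 + 3) % n_fill_m
        if a == b:
            b = (b + 1) % n_fill_m
        gene = f"g{j:04d}" if j < _BASE_GENES else ""
        model.add_reaction(
            Reaction(
                id=f"FILL{j:04d}",
                stoichiometry={f"f{a:04d}[c]": -1, f"f{b:04d}[c]": 1},
                reversible=True,
                gene_association=gene,
            )
        )
    return model
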