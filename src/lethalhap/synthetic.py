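"""Synthetic pedigrees, phased genotypes and breeding records.

Generates data with the statistical structure the downstream analyses
assume: an AI half-sib pedigree over a handful of overlapping generations,
gene-dropped phased genotypes in which one or more recessive lethal alleles
ride founder tag haplotypes at a few percent frequency, and calving /
insemination records whose failure and stillbirth processes respond to the
planted lethals (conception-acting lethals kill the conceptus so the cow
returns to service; birth-acting lethals yield stillborn calves, optionally
with incomplete penetrance).

Baseline stillbirth defaults to 26% for heifer calvings and 9.2% for later
parities.  Additive genetic values are simulated by pedigree gene-drop
(founders ~ N(0, s2u); offspring = parent average + Mendelian sampling) so
variance-component recovery tests have a known truth.  A failed conception
triggers re-insemination after 18-24 days.

All randomness derives from one master seed; each sub-simulation uses a
labelled child stream so stages are independently reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data_io import (
    MarkerMap,
    Pedigree,
    PhasedGenotypes,
    write_pedigree,
    write_phased_vcf,
)

DAY = pd.Timedelta(days=1)


class SimulationError(Exception):
    pass


def child_rng(seed: int, label: str) -> np.random.Generator:
    """Deterministic labelled child stream of the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(label.encode())])
    )


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass
class LethalSpec:
    """A recessive lethal riding a tag haplotype.

    ``window_span`` is a chromosome-local (start, end) marker index range
    (0-based, inclusive).  ``acts_at`` is "conception" (embryonic loss; the
    cow returns to service) or "birth" (stillbirth)."""

    chromosome: object
    window_span: tuple
    target_frequency: float
    acts_at: str = "conception"
    penetrance: float = 1.0
    tag_haplotype: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0.0 < self.target_frequency < 0.5:
            raise SimulationError("target_frequency must be in (0, 0.5)")
        if not 0.0 <= self.penetrance <= 1.0:
            raise SimulationError("penetrance must be in [0, 1]")
        if self.acts_at not in ("conception", "birth"):
            raise SimulationError("acts_at must be 'conception' or 'birth'")


@dataclass
class SimulationParams:
    n_founders: int = 100
    n_generations: int = 3
    sires_per_generation: int = 5
    daughters_per_sire: int = 8
    max_parities: int = 3
    n_chromosomes: int = 2
    markers_per_chromosome: int = 50
    marker_spacing_bp: int = 50_000
    founder_pool_size: int = 24
    recombination_rate_per_window: float = 0.2  # per chromosome per meiosis
    missing_rate: float = 0.0
    baseline_stillbirth_heifer: float = 0.26
    baseline_stillbirth_later: float = 0.092
    background_failure_f: float = 0.35
    sex_effect_stillbirth: float = 0.03
    month_effect_amplitude: float = 0.02
    variance_components: dict = field(
        default_factory=lambda: {
            "sb": {"maternal": 0.016, "direct": 0.015, "pe": 0.002},
            "fert": {"additive": 0.004, "pe": 0.01},
        }
    )
    n_herds: int = 10
    n_technicians: int = 8
    twin_rate: float = 0.01
    abortion_rate: float = 0.0
    infertility_rate: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        for name in (
            "recombination_rate_per_window", "missing_rate",
            "baseline_stillbirth_heifer", "baseline_stillbirth_later",
            "background_failure_f", "twin_rate", "abortion_rate", "infertility_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise SimulationError(f"{name} must be a probability, got {v}")
        for name in (
            "n_founders", "n_generations", "sires_per_generation",
            "daughters_per_sire", "n_chromosomes", "markers_per_chromosome",
        ):
            if getattr(self, name) < 1:
                raise SimulationError(f"{name} must be positive")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        names = {f.name for f in fields(cls)}
        unknown = set(d) - names
        if unknown:
            raise SimulationError(f"unknown simulation parameters: {sorted(unknown)}")
        return cls(**d)


# ---------------------------------------------------------------------------
# pedigree
# ---------------------------------------------------------------------------

def simulate_pedigree(params: SimulationParams) -> Pedigree:
    """Overlapping-generation AI pedigree.

    Founders form generation 0; each later generation is produced by a small
    team of AI sires drawn from the previous generation's males (large
    paternal half-sib families) and dams from the previous generation's
    females, each dam calving up to ``max_parities`` times.
    """
    rng = child_rng(params.seed, "pedigree")
    rows = []
    base = pd.Timestamp("2000-01-01")
    females: list[list[str]] = [[]]
    males: list[list[str]] = [[]]
    birth: dict[str, pd.Timestamp] = {}

    for i in range(params.n_founders):
        ind = f"G0-{i:05d}"
        sex = "M" if rng.random() < 0.35 else "F"
        bdate = base + int(rng.integers(0, 730)) * DAY
        rows.append((ind, "0", "0", sex, bdate.date().isoformat(), "G0"))
        birth[ind] = bdate
        (males if sex == "M" else females)[0].append(ind)

    n_calves_target = params.sires_per_generation * params.daughters_per_sire * 2
    for g in range(1, params.n_generations + 1):
        prev_f, prev_m = females[g - 1], males[g - 1]
        if len(prev_m) < params.sires_per_generation:
            raise SimulationError(
                f"generation {g-1} has {len(prev_m)} males; "
                f"cannot pick {params.sires_per_generation} sires"
            )
        if not prev_f:
            raise SimulationError(f"generation {g-1} has no females")
        calves_per_dam = -(-n_calves_target // len(prev_f))  # ceil
        if calves_per_dam > params.max_parities:
            raise SimulationError(
                f"infeasible family sizes: {calves_per_dam} calves per dam "
                f"exceeds max_parities={params.max_parities}"
            )
        sires = list(rng.choice(prev_m, size=params.sires_per_generation, replace=False))
        females.append([])
        males.append([])
        made = 0
        k = 0
        for dam in prev_f:
            n_this = min(calves_per_dam, n_calves_target - made)
            for parity in range(n_this):
                ind = f"G{g}-{k:05d}"
                k += 1
                sire = sires[int(rng.integers(len(sires)))]
                sex = "M" if rng.random() < 0.5 else "F"
                bdate = (
                    birth[dam]
                    + int(24 * 30.4375 + parity * 365 + rng.integers(-60, 61)) * DAY
                )
                rows.append((ind, sire, dam, sex, bdate.date().isoformat(), ""))
                birth[ind] = bdate
                (males if sex == "M" else females)[g].append(ind)
                made += 1
            if made >= n_calves_target:
                break
    table = pd.DataFrame(
        rows, columns=["individual", "sire", "dam", "sex", "birth_date", "upg"]
    )
    return Pedigree(table)


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def default_marker_map(params: SimulationParams) -> MarkerMap:
    rows = []
    for c in range(1, params.n_chromosomes + 1):
        for i in range(params.markers_per_chromosome):
            rows.append(
                (f"chr{c}:snp{i}", c, (i + 1) * params.marker_spacing_bp, "A", "B")
            )
    return MarkerMap(
        pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "ref", "alt"])
    )


def _global_span(marker_map: MarkerMap, spec: LethalSpec) -> tuple[int, int]:
    sl = marker_map.chromosome_slice(spec.chromosome)
    s, e = spec.window_span
    lo, hi = sl.start + s, sl.start + e
    if s < 0 or hi >= sl.stop:
        raise SimulationError(
            f"window_span {spec.window_span} outside chromosome {spec.chromosome}"
        )
    return lo, hi


def _resolve_tags(marker_map, lethal_specs, rng) -> list[np.ndarray]:
    tags = []
    for spec in lethal_specs:
        lo, hi = _global_span(marker_map, spec)
        if spec.tag_haplotype is not None:
            tag = np.asarray(spec.tag_haplotype, dtype=np.int8)
            if len(tag) != hi - lo + 1:
                raise SimulationError("tag_haplotype length does not match window_span")
        else:
            tag = rng.integers(0, 2, size=hi - lo + 1).astype(np.int8)
        tags.append(tag)
    return tags


def carrier_matrix(
    phased: PhasedGenotypes, lethal_specs: list, tags: list | None = None
) -> np.ndarray:
    """(n, 2, n_lethals) bool: haplotype h of individual i carries lethal l
    (identity with the tag haplotype over the lethal's window span)."""
    if tags is None:
        tags = [spec.tag_haplotype for spec in lethal_specs]
        if any(t is None for t in tags):
            raise SimulationError("lethal specs lack resolved tag haplotypes")
    n = phased.n_individuals
    out = np.zeros((n, 2, len(lethal_specs)), dtype=bool)
    for l, (spec, tag) in enumerate(zip(lethal_specs, tags)):
        lo, hi = _global_span(phased.marker_map, spec)
        seg = phased.haplotypes[:, :, lo : hi + 1]
        out[:, :, l] = (seg == np.asarray(tag, dtype=np.int8)).all(axis=2)
    return out


def simulate_genotypes(
    pedigree: Pedigree,
    params: SimulationParams,
    lethal_specs: list | None = None,
    marker_map: MarkerMap | None = None,
) -> PhasedGenotypes:
    """Gene-drop phased genotypes over the pedigree.

    Founder haplotypes are drawn from a chromosome-wise pool in which each
    lethal's tag haplotype segregates at its target frequency; gametes form
    with at most one crossover per chromosome at
    ``recombination_rate_per_window``.  A conceptus homozygous for a
    conception-acting lethal is redrawn with probability ``penetrance``
    (survivor sampling), so no live individual is homozygous for a fully
    penetrant conception lethal.  Resolved tag haplotypes are written back
    onto the specs.
    """
    lethal_specs = lethal_specs or []
    if marker_map is None:
        marker_map = default_marker_map(params)
    rng = child_rng(params.seed, "genotypes")
    m = marker_map.n_markers
    chrom_slices = [marker_map.chromosome_slice(c) for c in marker_map.chromosomes]

    tags = _resolve_tags(marker_map, lethal_specs, rng)
    for spec, tag in zip(lethal_specs, tags):
        spec.tag_haplotype = tag
    spans = [_global_span(marker_map, spec) for spec in lethal_specs]

    # founder pool: per-marker allele frequencies, then pool haplotypes
    freqs = rng.uniform(0.15, 0.85, size=m)
    pool = (rng.random((params.founder_pool_size, m)) < freqs).astype(np.int8)
    # keep non-carrier pool haplotypes off the tag by flipping one allele
    for (lo, hi), tag in zip(spans, tags):
        hits = np.flatnonzero((pool[:, lo : hi + 1] == tag).all(axis=1))
        for h in hits:
            pool[h, lo + int(rng.integers(hi - lo + 1))] ^= 1

    def founder_haplotype() -> np.ndarray:
        hap = pool[int(rng.integers(params.founder_pool_size))].copy()
        for spec, (lo, hi), tag in zip(lethal_specs, spans, tags):
            if rng.random() < spec.target_frequency:
                hap[lo : hi + 1] = tag
        return hap

    def gamete(parent_haps: np.ndarray) -> np.ndarray:
        out = np.empty(m, dtype=np.int8)
        for sl in chrom_slices:
            h0 = int(rng.integers(2))
            a, b = parent_haps[h0, sl], parent_haps[1 - h0, sl]
            if rng.random() < params.recombination_rate_per_window and sl.stop - sl.start > 1:
                k = int(rng.integers(1, sl.stop - sl.start))
                out[sl] = np.concatenate([a[:k], b[k:]])
            else:
                out[sl] = a
        return out

    conception = [
        (spec, lo, hi, tag)
        for spec, (lo, hi), tag in zip(lethal_specs, spans, tags)
        if spec.acts_at == "conception"
    ]

    sire_idx, dam_idx = pedigree.parent_indices()
    n = len(pedigree)
    haps = np.empty((n, 2, m), dtype=np.int8)
    for i in range(n):
        for attempt in range(200):
            g0 = gamete(haps[sire_idx[i]]) if sire_idx[i] >= 0 else founder_haplotype()
            g1 = gamete(haps[dam_idx[i]]) if dam_idx[i] >= 0 else founder_haplotype()
            dead = False
            for spec, lo, hi, tag in conception:
                if (
                    (g0[lo : hi + 1] == tag).all()
                    and (g1[lo : hi + 1] == tag).all()
                    and rng.random() < spec.penetrance
                ):
                    dead = True
                    break
            if not dead:
                break
        haps[i, 0] = g0
        haps[i, 1] = g1

    if params.missing_rate > 0:
        mask = rng.random(haps.shape) < params.missing_rate
        haps[mask] = -1
    return PhasedGenotypes(list(pedigree.individuals), haps, marker_map)


# ---------------------------------------------------------------------------
# breeding values
# ---------------------------------------------------------------------------

def drop_breeding_values(
    pedigree: Pedigree, sigma2: float, rng: np.random.Generator
) -> np.ndarray:
    """Pedigree gene-drop of additive values: founders ~ N(0, s2);
    offspring = parent average + Mendelian sampling N(0, s2/2)."""
    sire, dam = pedigree.parent_indices()
    n = len(pedigree)
    bv = np.empty(n)
    sd = np.sqrt(sigma2)
    for i in range(n):
        if sire[i] < 0 and dam[i] < 0:
            bv[i] = rng.normal(0.0, sd)
        else:
            pa = 0.5 * (
                (bv[sire[i]] if sire[i] >= 0 else 0.0)
                + (bv[dam[i]] if dam[i] >= 0 else 0.0)
            )
            bv[i] = pa + rng.normal(0.0, sd * np.sqrt(0.5))
    return bv


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

@dataclass
class PhenotypeTables:
    calvings: pd.DataFrame
    inseminations: pd.DataFrame
    cullings: pd.DataFrame
    breeding_values: dict

    def __iter__(self):  # allow (calvings, inseminations) unpacking
        return iter((self.calvings, self.inseminations))


def simulate_phenotypes(
    pedigree: Pedigree,
    genotypes: PhasedGenotypes,
    lethal_specs: list,
    params: SimulationParams,
) -> PhenotypeTables:
    """Simulate insemination and calving records consistent with the pedigree.

    For every pedigree calf, the failed inseminations that preceded its
    conception are simulated from the background failure rate plus the
    probability that a conceptus of that mating is a dead homozygote;
    conception-acting lethals therefore depress NRR56 in carrier x carrier
    matings while birth-acting lethals elevate stillbirth in calves that are
    homozygous by gene-drop.
    """
    rng = child_rng(params.seed, "phenotypes")
    carriers = carrier_matrix(genotypes, lethal_specs) if lethal_specs else None
    is_carrier = carriers.any(axis=1) if carriers is not None else None  # (n, L)
    is_hom = carriers.all(axis=1) if carriers is not None else None
    gidx = {ind: i for i, ind in enumerate(genotypes.individuals)}

    vc = params.variance_components
    bv_sb_m = drop_breeding_values(pedigree, vc["sb"]["maternal"], child_rng(params.seed, "bv-sb-m"))
    bv_sb_d = drop_breeding_values(pedigree, vc["sb"]["direct"], child_rng(params.seed, "bv-sb-d"))
    bv_fert = drop_breeding_values(pedigree, vc["fert"]["additive"], child_rng(params.seed, "bv-fert"))
    pe_sb = child_rng(params.seed, "pe-sb").normal(0, np.sqrt(vc["sb"]["pe"]), len(pedigree))
    pe_fert = child_rng(params.seed, "pe-fert").normal(0, np.sqrt(vc["fert"]["pe"]), len(pedigree))

    pidx = {ind: i for i, ind in enumerate(pedigree.individuals)}
    herd_rng = child_rng(params.seed, "herds")
    herd_of: dict = {}
    sire_col, dam_col = pedigree.table["sire"], pedigree.table["dam"]
    for i, ind in enumerate(pedigree.individuals):
        dam = dam_col.iloc[i]
        if dam in herd_of and herd_rng.random() < 0.9:
            herd_of[ind] = herd_of[dam]
        else:
            herd_of[ind] = f"H{int(herd_rng.integers(params.n_herds)):03d}"

    conception_l = [l for l, s in enumerate(lethal_specs) if s.acts_at == "conception"]
    birth_l = [l for l, s in enumerate(lethal_specs) if s.acts_at == "birth"]

    def conceptus_death_prob(sire, dam) -> float:
        if is_carrier is None or sire not in gidx or dam not in gidx:
            return 0.0
        prob_alive = 1.0
        for l in conception_l:
            if is_carrier[gidx[sire], l] and is_carrier[gidx[dam], l]:
                prob_alive *= 1.0 - 0.25 * lethal_specs[l].penetrance
        return 1.0 - prob_alive

    births = pd.to_datetime(pedigree.table["birth_date"])
    calv_rows, insem_rows, cull_rows = [], [], []
    calves = pedigree.table[pedigree.table["dam"] != "0"]
    order = births[calves.index].sort_values(kind="stable").index
    parity_count: dict = {}
    for ridx in order:
        row = pedigree.table.loc[ridx]
        calf, sire, dam = row["individual"], row["sire"], row["dam"]
        parity = parity_count.get(dam, 0)
        parity_count[dam] = parity + 1
        bdate = births[ridx]
        gestation = int(rng.integers(273, 288))
        conception = bdate - gestation * DAY

        q_bg = params.background_failure_f + bv_fert[pidx[dam]] + pe_fert[pidx[dam]]
        q_bg = float(np.clip(q_bg, 0.02, 0.95))
        q = 1.0 - (1.0 - q_bg) * (1.0 - conceptus_death_prob(sire, dam))
        n_failures = min(int(rng.geometric(1.0 - q)) - 1, 7)
        date = conception
        dates = [date]
        for _ in range(n_failures):
            date = date - int(rng.integers(18, 25)) * DAY
            dates.append(date)
        technician = f"T{int(rng.integers(params.n_technicians)):02d}"
        for d in reversed(dates):
            insem_rows.append(
                {
                    "cow": dam,
                    "date": d.date().isoformat(),
                    "technician": technician,
                    "lactation": min(parity, 3),
                    "herd": herd_of[dam],
                    "sire": sire,
                }
            )

        # stillbirth outcome
        dead = False
        if is_hom is not None and calf in gidx:
            for l in birth_l:
                if is_hom[gidx[calf], l] and rng.random() < lethal_specs[l].penetrance:
                    dead = True
                    break
        if not dead:
            base = (
                params.baseline_stillbirth_heifer
                if parity == 0
                else params.baseline_stillbirth_later
            )
            p_sb = (
                base
                + (params.sex_effect_stillbirth if row["sex"] == "M" else 0.0)
                + params.month_effect_amplitude * np.sin(2 * np.pi * bdate.month / 12.0)
                + bv_sb_m[pidx[dam]]
                + bv_sb_d[pidx[calf]]
                + pe_sb[pidx[dam]]
            )
            dead = rng.random() < float(np.clip(p_sb, 0.001, 0.999))
        if dead:
            outcome = ("stillborn", "died_during_calving", "died_within_24h")[
                int(rng.choice(3, p=(0.7, 0.2, 0.1)))
            ]
        else:
            outcome = "live"
        if params.abortion_rate > 0 and rng.random() < params.abortion_rate:
            outcome = "abortion"
        calv_rows.append(
            {
                "dam": dam,
                "sire": sire,
                "calf": calf,
                "date": bdate.date().isoformat(),
                "parity": parity,
                "calf_sex": row["sex"],
                "outcome": outcome,
                "twin": int(rng.random() < params.twin_rate),
                "herd": herd_of[dam],
            }
        )

    # infertility-culled cows: females without offspring get failed
    # inseminations and a culling record
    mothers = set(pedigree.table.loc[pedigree.table["dam"] != "0", "dam"])
    maidens = [
        ind
        for ind, sex in zip(pedigree.individuals, pedigree.table["sex"])
        if sex == "F" and ind not in mothers
    ]
    for ind in maidens:
        if rng.random() >= params.infertility_rate:
            continue
        start = births[pedigree.table.index[pidx[ind]]] + 450 * DAY
        technician = f"T{int(rng.integers(params.n_technicians)):02d}"
        date = start
        for _ in range(int(rng.integers(3, 7))):
            insem_rows.append(
                {
                    "cow": ind,
                    "date": date.date().isoformat(),
                    "technician": technician,
                    "lactation": 0,
                    "herd": herd_of[ind],
                    "sire": "0",
                }
            )
            date = date + int(rng.integers(18, 25)) * DAY
        cull_rows.append(
            {"cow": ind, "date": date.date().isoformat(), "reason": "infertility"}
        )

    calvings = pd.DataFrame(calv_rows)
    inseminations = pd.DataFrame(insem_rows)
    cullings = pd.DataFrame(cull_rows, columns=["cow", "date", "reason"])
    for df in (calvings, inseminations, cullings):
        if len(df):
            df["date"] = pd.to_datetime(df["date"])
    if len(calvings):
        calvings["twin"] = calvings["twin"].astype(bool)
    bvs = {
        "sb_maternal": dict(zip(pedigree.individuals, bv_sb_m)),
        "sb_direct": dict(zip(pedigree.individuals, bv_sb_d)),
        "fertility": dict(zip(pedigree.individuals, bv_fert)),
    }
    return PhenotypeTables(calvings, inseminations, cullings, bvs)


# ---------------------------------------------------------------------------
# fixture bundles
# ---------------------------------------------------------------------------

PRESETS = {
    "tiny": {
        "params": {
            "n_founders": 60,
            "n_generations": 2,
            "sires_per_generation": 4,
            "daughters_per_sire": 7,
            "n_chromosomes": 2,
            "markers_per_chromosome": 40,
            "founder_pool_size": 16,
        },
        "lethals": [
            {
                "chromosome": 1,
                "window_span": [0, 19],
                "target_frequency": 0.08,
                "acts_at": "conception",
                "penetrance": 1.0,
            }
        ],
    },
    "desk": {
        "params": {
            "n_founders": 1000,
            "n_generations": 3,
            "sires_per_generation": 60,
            "daughters_per_sire": 11,
            "n_chromosomes": 5,
            "markers_per_chromosome": 75,
            "founder_pool_size": 30,
            "recombination_rate_per_window": 0.1,
        },
        "lethals": [
            {
                "chromosome": 1,
                "window_span": [0, 24],
                "target_frequency": 0.06,
                "acts_at": "conception",
                "penetrance": 1.0,
            },
            {
                "chromosome": 3,
                "window_span": [25, 49],
                "target_frequency": 0.05,
                "acts_at": "birth",
                "penetrance": 0.9,
            },
        ],
    },
}


def load_preset(preset_name: str, seed: int) -> tuple[SimulationParams, list]:
    if preset_name not in PRESETS:
        raise SimulationError(f"unknown preset {preset_name!r}; choose from {sorted(PRESETS)}")
    cfg = PRESETS[preset_name]
    params = SimulationParams.from_dict({**cfg["params"], "seed": seed})
    lethals = [
        LethalSpec(
            chromosome=d["chromosome"],
            window_span=tuple(d["window_span"]),
            target_frequency=d["target_frequency"],
            acts_at=d["acts_at"],
            penetrance=d["penetrance"],
        )
        for d in cfg["lethals"]
    ]
    return params, lethals


def make_fixture_bundle(preset_name: str, seed: int, out_dir) -> dict:
    """Simulate a preset and write genotypes (phased VCF), pedigree and
    record CSVs to ``out_dir``; returns the file paths.  Byte-identical for
    the same preset and seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    params, lethals = load_preset(preset_name, seed)
    pedigree = simulate_pedigree(params)
    genotypes = simulate_genotypes(pedigree, params, lethals)
    tables = simulate_phenotypes(pedigree, genotypes, lethals, params)

    paths = {
        "genotypes": out_dir / "genotypes.vcf",
        "pedigree": out_dir / "pedigree.csv",
        "calvings": out_dir / "calvings.csv",
        "inseminations": out_dir / "inseminations.csv",
        "cullings": out_dir / "cullings.csv",
        "lethals": out_dir / "lethals.yaml",
    }
    write_phased_vcf(genotypes, paths["genotypes"])
    write_pedigree(pedigree, paths["pedigree"])
    for name in ("calvings", "inseminations", "cullings"):
        df = getattr(tables, name).copy()
        if len(df):
            df["date"] = df["date"].dt.date.astype(str)
        if "twin" in df.columns:
            df["twin"] = df["twin"].astype(int)
        df.to_csv(paths[name], index=False)
    with open(paths["lethals"], "w") as fh:
        yaml.safe_dump(
            [
                {
                    "chromosome": s.chromosome,
                    "window_span": list(s.window_span),
                    "target_frequency": s.target_frequency,
                    "acts_at": s.acts_at,
                    "penetrance": s.penetrance,
                    "tag_haplotype": [int(a) for a in s.tag_haplotype],
                }
                for s in lethals
            ],
            fh,
        )
    return {k: str(v) for k, v in paths.items()}
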