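import numpy as np
import pandas as pd
import pytest

from lethalhap import synthetic as syn
from lethalhap.data_io import MarkerMap, Pedigree, PhasedGenotypes


def make_marker_map(n_markers=5, chrom=1, spacing=1000):
    rows = [
        (f"chr{chrom}:snp{i}", chrom, (i + 1) * spacing, "A", "B")
        for i in range(n_markers)
    ]
    return MarkerMap(
        pd.DataFrame(rows, columns=["marker_id", "chromosome", "position_bp", "ref", "alt"])
    )


def make_phased(haps, chrom=1, individuals=None):
    """Build PhasedGenotypes from a list of (hapA, hapB) allele-list pairs."""
    haps = np.array(haps, dtype=np.int8)
    n, _, m = haps.shape
    if individuals is None:
        individuals = [f"ind{i}" for i in range(n)]
    return PhasedGenotypes(individuals, haps, make_marker_map(m, chrom=chrom))


def random_pedigree(rng, n, p_founder=0.3):
    """Random valid pedigree: each animal's parents drawn from earlier
    animals (inbreeding arises naturally)."""
    rows = []
    sexes = {}
    for i in range(n):
        ind = f"a{i}"
        males = [f"a{j}" for j in range(i) if sexes[f"a{j}"] == "M"]
        females = [f"a{j}" for j in range(i) if sexes[f"a{j}"] == "F"]
        if i < 4 or rng.random() < p_founder or not males or not females:
            sire = dam = "0"
        else:
            sire = males[int(rng.integers(len(males)))]
            dam = females[int(rng.integers(len(females)))]
        sex = "M" if rng.random() < 0.5 else "F"
        sexes[ind] = sex
        rows.append((ind, sire, dam, sex))
    return Pedigree(pd.DataFrame(rows, columns=["individual", "sire", "dam", "sex"]))


@pytest.fixture(scope="session")
def tiny_sim():
    """Shared tiny simulation with a fully penetrant conception lethal."""
    params, lethals = syn.load_preset("tiny", 7)
    pedigree = syn.simulate_pedigree(params)
    genotypes = syn.simulate_genotypes(pedigree, params, lethals)
    tables = syn.simulate_phenotypes(pedigree, genotypes, lethals, params)
    return {
        "params": params,
        "lethals": lethals,
        "pedigree": pedigree,
        "genotypes": genotypes,
        "tables": tables,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)
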