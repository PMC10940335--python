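import numpy as np
import pandas as pd
import pytest

from pedgxe.pedigree import Individual, Pedigree


def make_pedigree(rows):
    """rows: (id, father, mother, sex[, household]) tuples."""
    individuals = []
    for row in rows:
        iid, fa, mo, sex = row[:4]
        hh = row[4] if len(row) > 4 else None
        individuals.append(Individual(str(iid), fa, mo, sex, hh))
    return Pedigree(individuals)


@pytest.fixture
def trio():
    return make_pedigree([
        ("dad", None, None, "male", "h1"),
        ("mom", None, None, "female", "h1"),
        ("kid", "dad", "mom", "male", "h1"),
    ])


@pytest.fixture
def cousins_pedigree():
    """Two sibs married to unrelated spouses; their children are first cousins."""
    return make_pedigree([
        ("gpa", None, None, "male", "h0"),
        ("gma", None, None, "female", "h0"),
        ("sib1", "gpa", "gma", "male", "h1"),
        ("sib2", "gpa", "gma", "female", "h2"),
        ("sp1", None, None, "female", "h1"),
        ("sp2", None, None, "male", "h2"),
        ("c1", "sib1", "sp1", "male", "h1"),
        ("c2", "sp2", "sib2", "female", "h2"),
    ])


def random_pedigree(rng, max_founder_pairs=2, max_kids=3):
    """Random 3-generation pedigree of modest size for property tests."""
    rows = []
    counter = [0]

    def nid():
        counter[0] += 1
        return f"i{counter[0]}"

    couples = []
    for _ in range(rng.integers(1, max_founder_pairs + 1)):
        pa, ma = nid(), nid()
        rows.append((pa, None, None, "male", f"h{pa}"))
        rows.append((ma, None, None, "female", f"h{pa}"))
        couples.append((pa, ma, f"h{pa}"))
    for gen in range(2):
        nxt = []
        for pa, ma, hh in couples:
            for _ in range(rng.integers(1, max_kids + 1)):
                kid = nid()
                sex = "male" if rng.random() < 0.5 else "female"
                rows.append((kid, pa, ma, sex, hh))
                if gen == 0 and rng.random() < 0.6:
                    sp = nid()
                    sp_sex = "female" if sex == "male" else "male"
                    hh2 = f"h{kid}"
                    rows.append((sp, None, None, sp_sex, hh2))
                    nxt.append((kid, sp, hh2) if sex == "male" else (sp, kid, hh2))
        couples = nxt
    return make_pedigree(rows)


def gene_drop_kinship(ped, id_a, id_b, n_rep=100_000, seed=0):
    """Monte-Carlo additive relationship: drop distinct allele labels down the
    pedigree and estimate 2 * P(random alleles from a and b are IBD).

    Independent oracle for the recursive kinship computation.
    """
    rng = np.random.default_rng(seed)
    order = ped.topological_order()
    founders = [i for i in order if ped.is_founder(i)]
    label = {iid: k for k, iid in enumerate(founders)}
    # allele arrays: n_rep x 2 integer labels per individual
    alleles = {}
    next_label = 0
    for iid in founders:
        alleles[iid] = np.full((n_rep, 2), 0)
        alleles[iid][:, 0] = next_label
        alleles[iid][:, 1] = next_label + 1
        next_label += 2
    for iid in order:
        ind = ped[iid]
        if ind.father is None:
            continue
        pat = alleles[ind.father][np.arange(n_rep), rng.integers(0, 2, n_rep)]
        mat = alleles[ind.mother][np.arange(n_rep), rng.integers(0, 2, n_rep)]
        alleles[iid] = np.column_stack([pat, mat])
    a, b = alleles[id_a], alleles[id_b]
    ia = rng.integers(0, 2, n_rep)
    ib = rng.integers(0, 2, n_rep)
    ibd = a[np.arange(n_rep), ia] == b[np.arange(n_rep), ib]
    phat = ibd.mean()
    se = np.sqrt(phat * (1 - phat) / n_rep)
    return 2 * phat, 2 * se
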