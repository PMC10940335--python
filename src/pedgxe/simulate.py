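"""Synthetic extended-pedigree data generator.

Emulates the structure of a family study of ~42 extended families and
roughly 1,100-1,400 individuals recruited through probands and their
spouses: each simulated family contains two unrelated founder couples whose
offspring intermarry once (joining the proband's and the spouse's kin), the
remaining offspring marry in external spouses, and each married couple forms
its own household together with its children.

Trait values are drawn from the exact generative counterpart of the fitted
model: per family block, y = X beta + L eps with L the Cholesky factor of
the block covariance assembled from the true parameters, so simulated
moments match the likelihood's covariance model by construction.  Every
draw is a deterministic function of the scenario seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .covariance import GxEParams, ModelSpec, build_covariance, gxe_spec, model1_spec, model2_spec, sporadic_spec
from .pedigree import Individual, Pedigree, compute_kinship, family_blocks, household_matrix

__all__ = ["SimScenario", "simulate_pedigree", "simulate_zses",
           "simulate_covariates", "simulate_trait", "simulate_dataset",
           "scenario_presets"]


@dataclass(frozen=True)
class SimScenario:
    """Generative study design: family structure, environment, and truth.

    Defaults reproduce the scale of the emulated study: 42 extended families
    of two founder couples each, sibships of 1 + Poisson(mean_sibship - 1)
    children, offspring marrying in with probability ``p_marry``, three
    generations, one household per married couple.  zSES has a shared
    household component of SD ``tau`` on top of unit individual noise and is
    standardized to mean 0, SD 1.
    """

    n_families: int = 42
    founder_couples: int = 2
    mean_sibship: float = 3.5
    p_marry: float = 0.8
    generations: int = 3
    tau: float = 1.0                      # household-level zSES SD
    params: GxEParams = field(default_factory=lambda: GxEParams(
        alpha_g=np.log(0.45), alpha_e=np.log(0.55)))
    spec: ModelSpec = field(default_factory=model1_spec)
    beta_age: float = 0.0                 # per year, on the trait scale
    beta_sex: float = 0.0                 # female - male contrast
    prop_female: float = 0.57
    age_range: tuple[float, float] = (18.0, 94.0)
    seed: int = 0

    def __post_init__(self):
        if min(self.n_families, self.founder_couples, self.generations) < 1:
            raise ValueError("counts must be positive")
        if not 0 <= self.p_marry <= 1:
            raise ValueError("p_marry must be a probability")
        if self.tau < 0:
            raise ValueError("tau must be >= 0")

    def with_(self, **kw) -> "SimScenario":
        return replace(self, **kw)


def _rng(scenario: SimScenario, salt: int) -> np.random.Generator:
    return np.random.default_rng((scenario.seed, salt))


def simulate_pedigree(scenario: SimScenario) -> Pedigree:
    """Generate the family structure; deterministic given the seed.

    Per family: ``founder_couples`` unrelated founder couples produce
    Poisson sibships; with two or more couples, one offspring of the first
    couple marries one of the second (the proband-spouse link); remaining
    offspring marry external founders with probability ``p_marry`` and have
    children of their own, down to ``generations`` generations.  Households:
    every couple and its unmarried children share one household.
    """
    rng = _rng(scenario, 1)
    individuals: list[Individual] = []
    sib_mean = max(scenario.mean_sibship - 1.0, 0.0)

    for fam in range(scenario.n_families):
        fam_tag = f"F{fam + 1:03d}"
        counter = [0]

        def new_id():
            counter[0] += 1
            return f"{fam_tag}_{counter[0]:03d}"

        households = [0]

        def new_household():
            households[0] += 1
            return f"{fam_tag}_H{households[0]:02d}"

        def make_couple(spouse_of=None):
            """Create a couple (two founders, or one local + one founder)."""
            hh = new_household()
            if spouse_of is None:
                a, b = new_id(), new_id()
                individuals.append(Individual(a, None, None, "male", hh))
                individuals.append(Individual(b, None, None, "female", hh))
                return a, b, hh
            spouse = new_id()
            local_sex = sex_of[spouse_of]
            individuals.append(
                Individual(spouse, None, None,
                           "female" if local_sex == "male" else "male", hh))
            move_household(spouse_of, hh)
            if local_sex == "male":
                return spouse_of, spouse, hh
            return spouse, spouse_of, hh

        sex_of: dict[str, str] = {}
        hh_of: dict[str, str] = {}

        def move_household(iid, hh):
            hh_of[iid] = hh

        def add_children(father, mother, hh):
            n_kids = 0 if scenario.mean_sibship <= 0 else 1 + rng.poisson(sib_mean)
            kids = []
            for _ in range(n_kids):
                kid = new_id()
                kid_sex = "female" if rng.random() < 0.5 else "male"
                individuals.append(Individual(kid, father, mother, kid_sex, hh))
                sex_of[kid] = kid_sex
                hh_of[kid] = hh
                kids.append(kid)
            return kids

        # founder couples and their children (generation 2)
        offspring_sets = []
        for _ in range(scenario.founder_couples):
            pa, ma, hh = make_couple()
            sex_of[pa], sex_of[ma] = "male", "female"
            hh_of[pa] = hh_of[ma] = hh
            kids = add_children(pa, ma, hh) if scenario.generations >= 2 else []
            offspring_sets.append(kids)

        # the proband-spouse link: one cross-couple marriage when possible
        linked: list[tuple[str, str]] = []
        married: set[str] = set()
        if len(offspring_sets) >= 2 and offspring_sets[0] and offspring_sets[1]:
            a_cands = [k for k in offspring_sets[0]]
            b_cands = [k for k in offspring_sets[1] if sex_of[k] != sex_of[a_cands[0]]]
            if b_cands:
                a, b = a_cands[0], b_cands[0]
                linked.append((a, b) if sex_of[a] == "male" else (b, a))
                married |= {a, b}

        couples: list[tuple[str, str, str]] = []
        for pa_, ma_ in linked:
            hh = new_household()
            move_household(pa_, hh)
            move_household(ma_, hh)
            couples.append((pa_, ma_, hh))
        for kids in offspring_sets:
            for kid in kids:
                if kid in married:
                    continue
                if rng.random() < scenario.p_marry:
                    pa_, ma_, hh = make_couple(spouse_of=kid)
                    married.add(kid)
                    couples.append((pa_, ma_, hh))

        # subsequent generations
        current = couples
        for gen in range(3, scenario.generations + 1):
            next_couples = []
            for pa_, ma_, hh in current:
                kids = add_children(pa_, ma_, hh)
                if gen < scenario.generations:
                    for kid in kids:
                        if rng.random() < scenario.p_marry:
                            c = make_couple(spouse_of=kid)
                            next_couples.append(c)
            current = next_couples

        # rewrite households chosen after individuals were appended
        for idx in range(len(individuals)):
            ind = individuals[idx]
            if ind.iid in hh_of and ind.household != hh_of[ind.iid]:
                individuals[idx] = Individual(
                    ind.iid, ind.father, ind.mother, ind.sex, hh_of[ind.iid])

    return Pedigree(individuals)


def simulate_zses(ped: Pedigree, scenario: SimScenario) -> pd.Series:
    """Standardized SES score with a household-shared component.

    z_i = standardize(u_{household(i)} + v_i) with u ~ N(0, tau^2) per
    household and v ~ N(0, 1) per individual; output has mean 0, SD 1.
    """
    rng = _rng(scenario, 2)
    households = sorted({i.household for i in ped.individuals if i.household})
    u = dict(zip(households, rng.normal(0.0, scenario.tau, size=len(households))))
    v = rng.normal(0.0, 1.0, size=len(ped))
    raw = np.array([
        u.get(ind.household, 0.0) + v[k] for k, ind in enumerate(ped.individuals)
    ])
    z = (raw - raw.mean()) / raw.std(ddof=1)
    return pd.Series(z, index=ped.ids, name="zses")


def simulate_covariates(ped: Pedigree, scenario: SimScenario) -> pd.DataFrame:
    """Age (uniform over the study's 18-94 range) and sex covariates."""
    rng = _rng(scenario, 3)
    lo, hi = scenario.age_range
    age = rng.uniform(lo, hi, size=len(ped))
    sex = np.array([ind.sex for ind in ped.individuals])
    return pd.DataFrame(
        {"age": age, "female": (sex == "female").astype(float)}, index=ped.ids
    )


def simulate_trait(
    ped: Pedigree,
    z: pd.Series,
    covariates: pd.DataFrame | None,
    scenario: SimScenario,
    salt: int = 4,
) -> pd.Series:
    """Draw the trait from the block-diagonal MVN implied by the truth.

    Per family block: y_b = X_b beta + L_b eps with L_b the Cholesky factor
    of the covariance built from ``scenario.params`` / ``scenario.spec``.
    """
    rng = _rng(scenario, salt)
    kin = compute_kinship(ped)
    hh = household_matrix(ped)
    y = pd.Series(np.nan, index=ped.ids, name="y")
    for members in family_blocks(ped):
        ids = sorted(members)
        zb = z.loc[ids].to_numpy()
        omega = build_covariance(
            scenario.params, scenario.spec,
            kin.loc[ids, ids].to_numpy(), hh.loc[ids, ids].to_numpy(), zb,
        )
        try:
            chol = np.linalg.cholesky(omega)
        except np.linalg.LinAlgError as err:
            raise ValueError(
                f"covariance not positive definite in block {ids[0]!r} "
                f"under {scenario.params}"
            ) from err
        mean = np.zeros(len(ids))
        if covariates is not None:
            mean = (scenario.beta_age * covariates.loc[ids, "age"].to_numpy()
                    + scenario.beta_sex * covariates.loc[ids, "female"].to_numpy())
        y.loc[ids] = mean + chol @ rng.standard_normal(len(ids))
    return y


def simulate_dataset(scenario: SimScenario, n_traits: int = 1,
                     trait_names: list[str] | None = None) -> tuple[Pedigree, pd.DataFrame]:
    """Full dataset: pedigree plus a phenotype frame with id, zses,
    covariates, and one or more independent trait draws."""
    ped = simulate_pedigree(scenario)
    z = simulate_zses(ped, scenario)
    cov = simulate_covariates(ped, scenario)
    frame = pd.DataFrame({"id": ped.ids, "zses": z.to_numpy()})
    frame["age"] = cov["age"].to_numpy()
    frame["female"] = cov["female"].to_numpy()
    names = trait_names or (
        ["y"] if n_traits == 1 else [f"y{k + 1}" for k in range(n_traits)]
    )
    for k, name in enumerate(names):
        frame[name] = simulate_trait(ped, z, cov, scenario, salt=4 + k).to_numpy()
    return ped, frame


def scenario_presets(seed: int = 0) -> dict[str, SimScenario]:
    """Named generative scenarios used throughout the test battery.

    - ``null``: no genetic variance (pure residual noise).
    - ``polygenic``: homogeneous h^2 = 0.45, the study's fasting-glucose
      heritability scale.
    - ``variance-het``: genetic variance decreasing with zSES
      (gamma_g = -0.5) and genetic correlation decaying (lambda_g = 0.3) —
      genetic effects upregulated at the low end of the SES spectrum.
    - ``corr-decay``: correlation decay only (lambda_g = 0.5).
    - ``household-het``: household variance decreasing with zSES
      (gamma_c = -0.5), the systolic-blood-pressure pattern.
    """
    base = SimScenario(seed=seed)
    return {
        "null": base.with_(
            params=GxEParams(alpha_e=0.0), spec=sporadic_spec()),
        "polygenic": base.with_(
            params=GxEParams(alpha_g=np.log(0.45), alpha_e=np.log(0.55)),
            spec=model1_spec()),
        "variance-het": base.with_(
            params=GxEParams(alpha_g=np.log(0.45), gamma_g=-0.5, lambda_g=0.3,
                             alpha_e=np.log(0.55)),
            spec=gxe_spec()),
        "corr-decay": base.with_(
            params=GxEParams(alpha_g=np.log(0.45), lambda_g=0.5,
                             alpha_e=np.log(0.55)),
            spec=gxe_spec()),
        "household-het": base.with_(
            params=GxEParams(alpha_g=np.log(0.31), alpha_e=np.log(0.58),
                             alpha_c=np.log(0.11), gamma_c=-0.5),
            spec=gxe_spec(household=True)),
    }
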