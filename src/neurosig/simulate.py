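"""Synthetic cohorts with the statistical structure of a population-imaging study.

The generator emulates, at the post-preprocessing level, a biobank-style
case-control dataset with five mutually exclusive groups — healthy controls
(``CTRL``), major depressive disorder without comorbidity (``MDD``), anxiety
disorders without comorbidity (``ANX``), comorbid depression and anxiety
(``MDDANX``), and stress-related disorders (``STR``) — together with

* 210 functional-connectivity features (all unordered pairs of 21
  independent components),
* 360 regional cortical-thickness features,
* four cognitive test scores (TMT, Gf, PAL, DSST; TMT is a completion time,
  so larger means worse),
* three polygenic risk score columns, and
* covariates (age, sex, site, head motion) that genuinely confound the
  features.

Group effects are planted additively on the residual (post-covariate) scale
in units of ``noise_sd``, so a planted shift of ``d`` is, by construction,
the Cohen's d that a correctly specified case-control GLM estimates.  A
low-rank latent factor links connectivity to cognition so that the PLS stage
has a recoverable signal.  A single explicitly seeded RNG stream drives each
generate call; identical configs give bitwise-identical output.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

GROUPS = ("CTRL", "MDD", "ANX", "MDDANX", "STR")
CASE_GROUPS = ("MDD", "ANX", "MDDANX", "STR")
COGNITIVE_TESTS = ("TMT", "Gf", "PAL", "DSST")
PRS_COLUMNS = ("PRS_MDD", "PRS_ANX", "PRS_PTSD")

N_ICS = 21
N_CONNECTIVITY = N_ICS * (N_ICS - 1) // 2  # 210
N_THICKNESS = 360

# Study-scale demographics: group sizes, mean (sd) age, fraction female,
# mean (sd) head motion, active-symptom (PHQ-2 >= 2) and medication rates,
# and PRS group means (scores are standardised over the whole sample).
_GROUP_SIZES = {"CTRL": 21727, "MDD": 3233, "ANX": 664, "MDDANX": 676, "STR": 832}
_AGE_MEAN = {"CTRL": 63.8, "MDD": 62.4, "ANX": 63.5, "MDDANX": 62.5, "STR": 62.3}
_AGE_SD = {"CTRL": 7.5, "MDD": 7.5, "ANX": 7.2, "MDDANX": 7.7, "STR": 7.1}
_FEMALE_FRAC = {"CTRL": 0.50, "MDD": 0.64, "ANX": 0.62, "MDDANX": 0.66, "STR": 0.62}
_MOTION_MEAN = {"CTRL": 0.11, "MDD": 0.13, "ANX": 0.13, "MDDANX": 0.13, "STR": 0.12}
_MOTION_SD = {"CTRL": 0.05, "MDD": 0.06, "ANX": 0.07, "MDDANX": 0.07, "STR": 0.06}
_ACTIVE_RATE = {"CTRL": 0.08, "MDD": 0.30, "ANX": 0.16, "MDDANX": 0.34, "STR": 0.12}
_MEDICATED_RATE = {"CTRL": 0.06, "MDD": 0.45, "ANX": 0.55, "MDDANX": 0.65, "STR": 0.40}
_PRS_MEANS = {
    "PRS_MDD": {"CTRL": -0.03, "MDD": 0.15, "ANX": 0.09, "MDDANX": 0.18, "STR": -0.04},
    "PRS_ANX": {"CTRL": 0.0, "MDD": 0.04, "ANX": 0.0, "MDDANX": 0.11, "STR": -0.04},
    "PRS_PTSD": {"CTRL": 0.0, "MDD": 0.0, "ANX": 0.0, "MDDANX": 0.0, "STR": -0.09},
}

# Default cognitive group effects in SD units (positive TMT = slower = worse).
_COGNITIVE_EFFECTS = {
    "MDD": {"TMT": 0.06, "Gf": -0.05, "PAL": -0.04, "DSST": -0.12},
    "ANX": {"TMT": 0.12, "Gf": -0.14, "PAL": -0.13, "DSST": -0.11},
    "MDDANX": {"TMT": 0.19, "Gf": -0.16, "PAL": -0.05, "DSST": -0.28},
    "STR": {"TMT": 0.06, "Gf": -0.08, "PAL": -0.06, "DSST": -0.09},
}

_SITES = ("site_A", "site_B", "site_C")
_SITE_PROBS = (0.5, 0.3, 0.2)


def connectivity_feature_ids(n_ics: int = N_ICS) -> list[str]:
    """Labels for all unordered pairs of independent components.

    21 components yield 210 pairwise connectivity features.
    """
    return [f"IC{i + 1:02d}-IC{j + 1:02d}" for i, j in combinations(range(n_ics), 2)]


def thickness_feature_ids(n_regions: int = N_THICKNESS) -> list[str]:
    return [f"CT_{k + 1:03d}" for k in range(n_regions)]


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort draw.

    Parameters
    ----------
    n_per_group
        Participants per group.  Defaults are the study-scale group sizes
        (21,727 controls; 3,233 / 664 / 676 / 832 cases).
    effect_map
        ``{group: {"connectivity": array(210), "thickness": array(360),
        "cognition": array(4)}}`` of mean shifts in Cohen's d units on the
        post-covariate residual scale.  ``None`` builds a default map in
        which MDD, ANX, and MDDANX share ``shared_fraction`` of their
        affected imaging features (magnitude ~0.1, the study's effect-size
        range) while STR affects a disjoint subset; cognition effects are
        the study-scale standardized group deficits.
    shared_fraction
        Fraction of affected imaging features shared between the depressive
        and anxiety groups in the default effect map.
    latent_loadings
        ``(x_loadings, y_loadings)`` for each planted brain-cognition
        factor: a list of pairs, connectivity-side vector of length 210 and
        cognition-side vector of length 4.  ``None`` plants one rank-1
        factor: 20 connectivity features at +/-0.5 and cognition loadings
        (0.18, -0.18, -0.18, -0.18), i.e. ~3% of the variance of each test.
    latent_strength
        Global multiplier on every planted factor's contribution.
    confound_coefficients
        Scales of the covariate effects on features and cognition; each
        feature's coefficient for covariate c is drawn N(0, scale_c^2).
        Motion affects connectivity only.
    prs_feature_coefficients
        Optional ``{prs_column: {"connectivity": array, "thickness": array}}``
        planting a genetically mediated feature shift proportional to the
        participant's PRS (used for shared-genetics scenarios).
    block_correlation
        Within-block residual correlation of the imaging features (features
        are partitioned into network-style blocks); a modelling choice, as
        the true covariance of real connectivity panels is not prescribed.
    noise_sd
        Residual scale of the imaging features.
    cognition_missing_rate
        Per-cell completely-at-random missingness of the cognitive tests
        (default 0.12, which leaves ~60% of cases complete on all four).
    seed
        Fully determines the draw.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: dict(_GROUP_SIZES))
    effect_map: dict | None = None
    shared_fraction: float = 0.5
    n_affected: dict[str, int] = field(
        default_factory=lambda: {"connectivity": 40, "thickness": 60}
    )
    effect_size: float = 0.1
    latent_loadings: list[tuple[np.ndarray, np.ndarray]] | None = None
    latent_strength: float = 1.0
    confound_coefficients: dict[str, float] = field(
        default_factory=lambda: {"age": 0.01, "sex": 0.05, "motion": 0.5, "site": 0.05}
    )
    prs_feature_coefficients: dict | None = None
    block_correlation: float = 0.2
    noise_sd: float = 1.0
    cognition_missing_rate: float = 0.12
    seed: int = 0

    def validate(self) -> None:
        for g, n in self.n_per_group.items():
            if g not in GROUPS:
                raise ValueError(f"unknown group {g!r}; expected one of {GROUPS}")
            if n < 2:
                raise ValueError(f"n_per_group[{g!r}] = {n} < 2")
        for frac_name in ("shared_fraction", "cognition_missing_rate"):
            v = getattr(self, frac_name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{frac_name} = {v} outside [0, 1]")
        if not 0.0 <= self.block_correlation < 1.0:
            raise ValueError("block_correlation must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.latent_loadings is not None:
            for xl, yl in self.latent_loadings:
                if len(np.asarray(xl)) != N_CONNECTIVITY:
                    raise ValueError(
                        f"connectivity-side loading length {len(np.asarray(xl))} "
                        f"!= {N_CONNECTIVITY}"
                    )
                if len(np.asarray(yl)) != len(COGNITIVE_TESTS):
                    raise ValueError("cognition-side loading length != 4")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _default_effect_map(cfg: SimulationConfig, rng: np.random.Generator) -> dict:
    """Plant overlapping signatures for MDD/ANX/MDDANX and a disjoint STR one."""
    out: dict[str, dict[str, np.ndarray]] = {g: {} for g in CASE_GROUPS}
    for modality, m in (("connectivity", N_CONNECTIVITY), ("thickness", N_THICKNESS)):
        k = cfg.n_affected[modality]
        pool = rng.permutation(m)
        core = pool[:k]  # MDD's affected set
        n_shared = int(round(cfg.shared_fraction * k))
        signs = rng.choice([-1.0, 1.0], size=m)
        shared = core[:n_shared]
        own_sets = {
            "MDD": core[n_shared:],
            "ANX": pool[k : 2 * k - n_shared],
            "MDDANX": pool[2 * k - n_shared : 3 * k - 2 * n_shared],
        }
        for g, scale in (("MDD", 1.0), ("ANX", 1.0), ("MDDANX", 1.3)):
            vec = np.zeros(m)
            idx = np.concatenate([shared, own_sets[g]]).astype(int)
            vec[idx] = cfg.effect_size * scale * signs[idx]
            out[g][modality] = vec
        # STR: small disjoint signature
        str_k = max(4, k // 4)
        str_idx = pool[-str_k:]
        vec = np.zeros(m)
        vec[str_idx] = cfg.effect_size * signs[str_idx]
        out["STR"][modality] = vec
    for g in CASE_GROUPS:
        out[g]["cognition"] = np.array(
            [_COGNITIVE_EFFECTS[g][t] for t in COGNITIVE_TESTS]
        )
    return out


def _default_latent(cfg, rng) -> list[tuple[np.ndarray, np.ndarray]]:
    x = np.zeros(N_CONNECTIVITY)
    support = rng.choice(N_CONNECTIVITY, size=20, replace=False)
    x[support] = rng.choice([-0.5, 0.5], size=20)
    y = np.array([0.18, -0.18, -0.18, -0.18])
    return [(x, y)]


def _feature_blocks(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Block labels inducing a network-style residual correlation structure.

    Each of the 21 components is assigned to one of 9 modules (7 cortical
    networks, cerebellum, striatum); a connectivity feature's block is its
    unordered module pair.  Thickness regions fall into 12 contiguous blocks.
    """
    ic_module = rng.integers(0, 9, size=N_ICS)
    conn_block = np.array(
        [
            hash(tuple(sorted((ic_module[i], ic_module[j])))) % (1 << 30)
            for i, j in combinations(range(N_ICS), 2)
        ]
    )
    # renumber blocks 0..B-1
    _, conn_block = np.unique(conn_block, return_inverse=True)
    thick_block = np.repeat(np.arange(12), N_THICKNESS // 12)
    return conn_block, thick_block


def _correlated_noise(rng, n, blocks, rho, sd):
    """iid-N(0, sd^2) marginals with correlation rho within each block."""
    eps = rng.standard_normal((n, len(blocks)))
    if rho <= 0:
        return sd * eps
    n_blocks = blocks.max() + 1
    shared = rng.standard_normal((n, n_blocks))
    return sd * (np.sqrt(rho) * shared[:, blocks] + np.sqrt(1.0 - rho) * eps)


def _covariate_effects(rng, cohort, feature_count, coefs, with_motion):
    """Confound contribution: per-feature coefficients drawn once per call."""
    age_c = cohort["age"].to_numpy(float) - cohort["age"].to_numpy(float).mean()
    parts = []
    beta_age = rng.normal(0.0, coefs.get("age", 0.0), feature_count)
    parts.append(np.outer(age_c, beta_age))
    beta_sex = rng.normal(0.0, coefs.get("sex", 0.0), feature_count)
    parts.append(np.outer(cohort["sex"].to_numpy(float), beta_sex))
    if with_motion:
        beta_mot = rng.normal(0.0, coefs.get("motion", 0.0), feature_count)
        motion_c = cohort["motion"].to_numpy(float)
        parts.append(np.outer(motion_c - motion_c.mean(), beta_mot))
    site_codes = pd.Categorical(cohort["site"]).codes
    site_offsets = rng.normal(0.0, coefs.get("site", 0.0), (site_codes.max() + 1, feature_count))
    parts.append(site_offsets[site_codes])
    return sum(parts)


def generate_cohort(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw one full synthetic cohort.

    Returns
    -------
    cohort : DataFrame
        One row per participant: ``participant_id`` (index), ``group``,
        ``age`` (integer years), ``sex`` (1 = female), ``site``, ``motion``,
        ``active_symptom_flag``, ``medicated_flag``, and the three PRS
        columns.
    connectivity, thickness : DataFrame
        Participants x features panels (210 and 360 columns).
    cognition : DataFrame
        Participants x 4 test scores, NaN where missing.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    groups = [g for g in GROUPS if config.n_per_group.get(g, 0) > 0]
    rows = []
    for g in groups:
        n = config.n_per_group[g]
        age = np.clip(np.round(rng.normal(_AGE_MEAN[g], _AGE_SD[g], n)), 45, 82).astype(int)
        sex = (rng.random(n) < _FEMALE_FRAC[g]).astype(int)
        site = rng.choice(_SITES, size=n, p=_SITE_PROBS)
        motion = np.maximum(rng.normal(_MOTION_MEAN[g], _MOTION_SD[g], n), 0.01)
        active = (rng.random(n) < _ACTIVE_RATE[g]).astype(int)
        medicated = (rng.random(n) < _MEDICATED_RATE[g]).astype(int)
        df = pd.DataFrame(
            {
                "group": g,
                "age": age,
                "sex": sex,
                "site": site,
                "motion": motion,
                "active_symptom_flag": active,
                "medicated_flag": medicated,
            }
        )
        for prs in PRS_COLUMNS:
            df[prs] = rng.normal(_PRS_MEANS[prs][g], 1.0, n)
        rows.append(df)
    cohort = pd.concat(rows, ignore_index=True)
    cohort.index = pd.Index(
        [f"P{k:06d}" for k in range(len(cohort))], name="participant_id"
    )

    n_total = len(cohort)
    effect_map = config.effect_map
    if effect_map is None:
        effect_map = _default_effect_map(config, rng)
    latents = config.latent_loadings
    if latents is None:
        latents = _default_latent(config, rng)
    u = rng.standard_normal((n_total, len(latents)))

    conn_block, thick_block = _feature_blocks(rng)
    group_arr = cohort["group"].to_numpy()

    panels = {}
    for modality, ids, blocks, with_motion in (
        ("connectivity", connectivity_feature_ids(), conn_block, True),
        ("thickness", thickness_feature_ids(), thick_block, False),
    ):
        m = len(ids)
        values = _covariate_effects(
            rng, cohort, m, config.confound_coefficients, with_motion
        )
        values += _correlated_noise(
            rng, n_total, blocks, config.block_correlation, config.noise_sd
        )
        for g, shifts in effect_map.items():
            vec = np.asarray(shifts.get(modality, np.zeros(m)), float)
            if vec.shape != (m,):
                raise ValueError(
                    f"effect_map[{g!r}][{modality!r}] has length {vec.size}, expected {m}"
                )
            values[group_arr == g] += config.noise_sd * vec
        if modality == "connectivity":
            for k, (xl, _) in enumerate(latents):
                values += config.latent_strength * np.outer(u[:, k], np.asarray(xl, float))
        if config.prs_feature_coefficients:
            for prs_col, coefs in config.prs_feature_coefficients.items():
                vec = np.asarray(coefs.get(modality, np.zeros(m)), float)
                values += np.outer(cohort[prs_col].to_numpy(float), vec)
        panels[modality] = pd.DataFrame(values, index=cohort.index, columns=ids)

    cog = _covariate_effects(
        rng, cohort, len(COGNITIVE_TESTS), config.confound_coefficients, False
    )
    cog += rng.standard_normal((n_total, len(COGNITIVE_TESTS)))
    for g, shifts in effect_map.items():
        vec = np.asarray(shifts.get("cognition", np.zeros(len(COGNITIVE_TESTS))), float)
        cog[group_arr == g] += vec
    for k, (_, yl) in enumerate(latents):
        cog += config.latent_strength * np.outer(u[:, k], np.asarray(yl, float))
    cognition = pd.DataFrame(cog, index=cohort.index, columns=list(COGNITIVE_TESTS))
    if config.cognition_missing_rate > 0:
        mask = rng.random(cognition.shape) < config.cognition_missing_rate
        cognition = cognition.mask(mask)

    return cohort, panels["connectivity"], panels["thickness"], cognition


def generate_genotypes(
    n_participants: int,
    n_variants: int,
    maf: np.ndarray | float,
    missing_rate: float = 0.0,
    ld_blocks: np.ndarray | None = None,
    ld_rho: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Allele-count matrix with allele-frequency and LD-block structure.

    Each haplotype allele is a thresholded Gaussian: within an LD block the
    latent Gaussians share a common factor with correlation ``ld_rho``, so
    genotype correlation is higher within blocks than between them.

    Returns a participants x variants DataFrame with entries in {0, 1, 2}
    (count of minor/effect alleles) and NaN for missing calls.
    """
    rng = np.random.default_rng(seed)
    maf = np.broadcast_to(np.asarray(maf, float), (n_variants,))
    if np.any(maf <= 0) or np.any(maf > 0.5):
        raise ValueError("maf must lie in (0, 0.5]")
    if not 0.0 <= missing_rate < 1.0:
        raise ValueError("missing_rate must be in [0, 1)")
    if ld_blocks is None:
        ld_blocks = np.arange(n_variants)
    ld_blocks = np.asarray(ld_blocks)
    if ld_blocks.shape != (n_variants,):
        raise ValueError("ld_blocks must assign one block per variant")
    if not 0.0 <= ld_rho < 1.0:
        raise ValueError("within-block correlation must be in [0, 1)")

    _, block_idx = np.unique(ld_blocks, return_inverse=True)
    n_blocks = block_idx.max() + 1
    thresh = stats.norm.ppf(maf)
    geno = np.zeros((n_participants, n_variants))
    for _hap in range(2):
        shared = rng.standard_normal((n_participants, n_blocks))
        z = np.sqrt(ld_rho) * shared[:, block_idx] + np.sqrt(1.0 - ld_rho) * (
            rng.standard_normal((n_participants, n_variants))
        )
        geno += (z < thresh).astype(float)
    if missing_rate > 0:
        geno[rng.random(geno.shape) < missing_rate] = np.nan
    return pd.DataFrame(
        geno,
        index=pd.Index([f"P{k:06d}" for k in range(n_participants)], name="participant_id"),
        columns=[f"rs{k + 1}" for k in range(n_variants)],
    )


@dataclass
class NetworkAssignment:
    """Outcome of mapping a component's spatial map onto an atlas."""

    label: str | None
    proportions: pd.Series
    n_suprathreshold: int

    @property
    def assignable(self) -> bool:
        return self.label is not None


def assign_network_label(
    component_mask: np.ndarray,
    atlas_labels: np.ndarray,
    threshold: float = 3.0,
) -> NetworkAssignment:
    """Assign a component to the network holding most of its strong voxels.

    Voxels with score strictly above ``threshold`` (z > 3 by default) are
    counted per atlas network; the component is labelled with the argmax.
    Voxels outside every network (atlas label ``None``, empty, ``'none'`` or
    ``0``) fall in an ``"unassigned"`` bin that participates in the
    proportions (which sum to 1) but never wins the label.  If no voxel
    exceeds the threshold the component is explicitly unassignable.
    """
    component_mask = np.asarray(component_mask, float)
    atlas_labels = np.asarray(atlas_labels, object)
    if component_mask.shape != atlas_labels.shape:
        raise ValueError("component mask and atlas must have the same length")
    supra = component_mask > threshold
    n_supra = int(supra.sum())
    if n_supra == 0:
        return NetworkAssignment(None, pd.Series(dtype=float), 0)
    labels = np.array(
        [
            "unassigned" if (lab is None or lab == "" or lab == "none" or lab == 0) else str(lab)
            for lab in atlas_labels[supra]
        ]
    )
    counts = pd.Series(labels).value_counts()
    proportions = (counts / n_supra).sort_index()
    in_network = proportions.drop("unassigned", errors="ignore")
    label = None if in_network.empty else in_network.idxmax()
    return NetworkAssignment(label, proportions, n_supra)
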