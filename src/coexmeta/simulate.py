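"""Synthetic multi-study expression data with known ground truth.

The generators emulate the structure of a ten-study lung meta-analysis: six
lung-cancer (LC) case/control studies and four other-lung-disease (LD)
studies, each a raw-intensity feature x sample matrix with additive plus
multiplicative noise, a globally-consistent planted set of differentially
expressed "winner" genes, latent-factor correlated gene blocks for network
analysis, and survival cohorts whose hazard depends on an expression split.

Seeding follows a fixed splitting rule: one root seed spawns per-study child
seeds via :class:`numpy.random.SeedSequence.spawn`, so adding a study never
changes earlier studies and every generator is a pure function of its seeds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .datatypes import ExpressionStudy
from .errors import ConfigurationError
from .survival import SurvivalCohort

# Per-study (control, case) sizes mirroring a typical published ten-study
# lung design: six LC studies then four LD studies.
DEFAULT_GROUP_SIZES: tuple[tuple[int, int], ...] = (
    (60, 60), (49, 58), (5, 5), (9, 54), (18, 22), (30, 30),  # LC
    (12, 42), (12, 18), (11, 13), (11, 15),                   # LD
)

# Raw intensities are clipped at this positive floor before export,
# mimicking scanner output that never reports non-positive signal.
INTENSITY_FLOOR = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic multi-study generator.

    ``effect_size`` is the planted case-vs-control mean shift in glog2 units
    (implemented as a fold change of ``2**effect_size`` on the raw scale,
    which converges to that glog2 shift for intensities well above the glog
    calibration constant). ``winner_penetrance`` is the probability that a
    planted winner is actually perturbed in any given study.
    """

    n_lc_studies: int = 6
    n_ld_studies: int = 4
    n_genes: int = 800
    samples_per_group: int | tuple[int, int] | None = None  # None -> Table-like sizes
    n_winner_up: int = 40
    n_winner_down: int = 30
    effect_size: float = 2.0
    winner_penetrance: float = 1.0
    n_blocks: int = 5
    block_size: int = 20
    within_block_r: float = 0.8
    between_block_r: float = 0.1
    shared_block_fraction: float = 1.0
    additive_sd: float = 15.0
    multiplicative_sd: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_lc_studies", "n_ld_studies", "n_genes", "n_blocks",
                     "block_size"):
            if int(getattr(self, name)) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("n_winner_up", "n_winner_down"):
            if int(getattr(self, name)) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        for name in ("winner_penetrance", "shared_block_fraction"):
            v = float(getattr(self, name))
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.between_block_r < self.within_block_r <= 1.0:
            raise ConfigurationError(
                "require 0 <= between_block_r < within_block_r <= 1"
            )
        if self.n_blocks * self.block_size > self.n_genes:
            raise ConfigurationError("n_blocks * block_size exceeds n_genes")
        if self.n_winner_up + self.n_winner_down > self.n_genes:
            raise ConfigurationError("planted winners exceed n_genes")
        if self.additive_sd < 0 or self.multiplicative_sd < 0:
            raise ConfigurationError("noise_model sds must be non-negative")
        if self.samples_per_group is not None:
            spg = self.samples_per_group
            if isinstance(spg, tuple):
                if len(spg) != 2 or spg[0] < 2 or spg[1] < spg[0]:
                    raise ConfigurationError(
                        "samples_per_group range must be (low, high), low >= 2"
                    )
            elif int(spg) < 2:
                raise ConfigurationError("samples_per_group must be >= 2")


@dataclass
class SimulationTruth:
    """Ground truth attached to a generated dataset."""

    planted_up: set[str] = field(default_factory=set)
    planted_down: set[str] = field(default_factory=set)
    block_membership: dict[str, int] = field(default_factory=dict)
    shared_blocks: set[int] = field(default_factory=set)
    true_hr: float | None = None

    def __post_init__(self) -> None:
        overlap = self.planted_up & self.planted_down
        if overlap:
            raise ConfigurationError(
                f"genes planted in both directions: {sorted(overlap)[:5]}"
            )

    def within_block_edges(self, blocks: set[int] | None = None) -> set[tuple[str, str]]:
        """All unordered within-block gene pairs, optionally restricted."""
        members: dict[int, list[str]] = {}
        for g, b in self.block_membership.items():
            members.setdefault(b, []).append(g)
        edges: set[tuple[str, str]] = set()
        for b, genes in members.items():
            if blocks is not None and b not in blocks:
                continue
            genes = sorted(genes)
            for i in range(len(genes)):
                for j in range(i + 1, len(genes)):
                    edges.add((genes[i], genes[j]))
        return edges


def gene_labels(n_genes: int) -> list[str]:
    return [f"G{i:05d}" for i in range(n_genes)]


def global_winner_truth(config: SimulationConfig) -> tuple[set[str], set[str]]:
    """The designated global winner sets (direction fixed across studies)."""
    labels = gene_labels(config.n_genes)
    up = set(labels[: config.n_winner_up])
    down = set(labels[config.n_winner_up: config.n_winner_up + config.n_winner_down])
    return up, down


def _group_sizes(config: SimulationConfig, study_index: int,
                 rng: np.random.Generator) -> tuple[int, int]:
    spg = config.samples_per_group
    if spg is None:
        n_ctrl, n_case = DEFAULT_GROUP_SIZES[study_index % len(DEFAULT_GROUP_SIZES)]
        return n_ctrl, n_case
    if isinstance(spg, tuple):
        lo, hi = spg
        n = int(rng.integers(lo, hi + 1))
        return n, n
    return int(spg), int(spg)


def gen_expression_study(
    config: SimulationConfig,
    disease_class: str,
    study_seed: int | np.random.SeedSequence,
    study_id: str = "S1",
    study_index: int = 0,
) -> tuple[ExpressionStudy, SimulationTruth]:
    """Generate one raw-intensity case/control study with planted winners.

    The intensity model is ``y = alpha + mu * exp(eta) + eps`` with per-gene
    log-normal baselines ``mu``, multiplicative noise ``eta`` and additive
    noise ``eps``. In the case group each planted winner is perturbed, with
    probability ``winner_penetrance``, by a fold change of
    ``2**(+-effect_size)`` applied to its baseline.
    """
    rng = np.random.default_rng(study_seed)
    labels = gene_labels(config.n_genes)
    up_all, down_all = global_winner_truth(config)

    n_ctrl, n_case = _group_sizes(config, study_index, rng)
    mu = rng.lognormal(mean=6.0, sigma=1.0, size=config.n_genes)

    fires = rng.random(config.n_genes) < config.winner_penetrance
    shift = np.zeros(config.n_genes)
    planted_up, planted_down = set(), set()
    for i, g in enumerate(labels):
        if not fires[i]:
            continue
        if g in up_all:
            shift[i] = config.effect_size
            planted_up.add(g)
        elif g in down_all:
            shift[i] = -config.effect_size
            planted_down.add(g)

    n = n_ctrl + n_case
    eta = rng.normal(0.0, config.multiplicative_sd, size=(config.n_genes, n))
    eps = rng.normal(0.0, config.additive_sd, size=(config.n_genes, n))
    baseline = np.tile(mu[:, None], (1, n))
    baseline[:, n_ctrl:] *= 2.0 ** shift[:, None]
    alpha = 30.0
    y = alpha + baseline * np.exp(eta) + eps
    y = np.maximum(y, INTENSITY_FLOOR)

    samples = [f"{study_id}_N{k:03d}" for k in range(n_ctrl)] + [
        f"{study_id}_T{k:03d}" for k in range(n_case)
    ]
    group = pd.Series(["control"] * n_ctrl + ["case"] * n_case, index=samples)
    study = ExpressionStudy(
        study_id=study_id,
        disease_class=disease_class,
        values=pd.DataFrame(y, index=labels, columns=samples),
        group=group,
        scale="raw",
    )
    truth = SimulationTruth(planted_up=planted_up, planted_down=planted_down)
    return study, truth


def gen_study_collection(
    config: SimulationConfig,
) -> list[tuple[ExpressionStudy, SimulationTruth]]:
    """Generate the full LC + LD collection from one root seed.

    The same globally-directed winner set is planted in every study (where
    penetrance fires), so downstream consensus recovery is testable against
    :func:`global_winner_truth`.
    """
    n_total = config.n_lc_studies + config.n_ld_studies
    children = np.random.SeedSequence(config.seed).spawn(n_total)
    out = []
    for i in range(n_total):
        cls = "LC" if i < config.n_lc_studies else "LD"
        k = i if cls == "LC" else i - config.n_lc_studies
        sid = f"{cls}{k + 1}"
        out.append(
            gen_expression_study(config, cls, children[i], study_id=sid,
                                 study_index=i)
        )
    return out


def gen_coexpression_pair(
    config: SimulationConfig,
) -> tuple[ExpressionStudy, ExpressionStudy, SimulationTruth]:
    """Two glog2-scale studies with partially shared correlated gene blocks.

    Gene *i* in block *b* follows the latent-factor model
    ``x = mu_i + lam * f_b + sigma * e`` with ``lam`` tuned so the within-block
    correlation equals ``within_block_r``; block factors share a common
    component so between-block correlation targets ``between_block_r``.
    Blocks listed in ``truth.shared_blocks`` keep their structure in the
    second study; genes of non-shared blocks are scrambled to independent
    noise there.
    """
    if config.within_block_r >= 1.0:
        raise ConfigurationError(
            "within_block_r must be < 1 to be reachable under noise"
        )
    root = np.random.SeedSequence(config.seed).spawn(2)
    spg = config.samples_per_group
    n_samples = 2 * int(spg) if isinstance(spg, int) else 60
    labels = gene_labels(config.n_genes)

    membership: dict[str, int] = {}
    for b in range(config.n_blocks):
        for j in range(config.block_size):
            membership[labels[b * config.block_size + j]] = b
    n_shared = int(round(config.shared_block_fraction * config.n_blocks))
    shared = set(range(n_shared))

    sigma = 1.0
    lam = sigma * math.sqrt(config.within_block_r / (1.0 - config.within_block_r))
    rho_f = (config.between_block_r / config.within_block_r
             if config.within_block_r > 0 else 0.0)

    def one_study(seed_seq: np.random.SeedSequence, sid: str,
                  keep_blocks: set[int]) -> ExpressionStudy:
        rng = np.random.default_rng(seed_seq)
        mu = rng.normal(8.0, 1.0, size=config.n_genes)
        g = rng.normal(size=n_samples)  # common factor component
        h = rng.normal(size=(config.n_blocks, n_samples))
        f = math.sqrt(rho_f) * g[None, :] + math.sqrt(1.0 - rho_f) * h
        x = mu[:, None] + sigma * rng.normal(size=(config.n_genes, n_samples))
        for i, lab in enumerate(labels):
            b = membership.get(lab)
            if b is not None and b in keep_blocks:
                x[i] += lam * f[b]
        samples = [f"{sid}_S{k:03d}" for k in range(n_samples)]
        half = n_samples // 2
        group = pd.Series(["control"] * half + ["case"] * (n_samples - half),
                          index=samples)
        return ExpressionStudy(
            study_id=sid, disease_class="LC",
            values=pd.DataFrame(x, index=labels, columns=samples),
            group=group, scale="glog2",
        )

    all_blocks = set(range(config.n_blocks))
    study_a = one_study(root[0], "NETA", all_blocks)
    study_b = one_study(root[1], "NETB", shared)
    truth = SimulationTruth(block_membership=membership, shared_blocks=shared)
    return study_a, study_b, truth


def gen_survival_cohort(
    n: int,
    true_hr: float,
    censor_rate: float,
    seed: int,
    with_covariates: bool = False,
) -> SurvivalCohort:
    """Survival cohort whose hazard depends on an expression median split.

    Event times are exponential; subjects whose expression lies above the
    cohort median ("high") have hazard ``true_hr`` times the low group's.
    Censoring is independent uniform on ``(0, c)`` with ``c`` solved per
    group so the expected censored fraction equals ``censor_rate``.
    """
    if n < 2:
        raise ConfigurationError("n must be >= 2")
    if true_hr <= 0:
        raise ConfigurationError("true_hr must be positive")
    if not 0.0 <= censor_rate < 1.0:
        raise ConfigurationError("censor_rate must lie in [0, 1)")

    rng = np.random.default_rng(seed)
    expression = rng.normal(0.0, 1.0, size=n)
    high = expression > np.median(expression)
    base_rate = 0.1
    rate = np.where(high, base_rate * true_hr, base_rate)
    event_time = rng.exponential(1.0 / rate)

    if censor_rate > 0.0:
        # solve (1 - exp(-x)) / x = censor_rate for x = rate * c
        x = brentq(lambda t: (1.0 - math.exp(-t)) / t - censor_rate, 1e-12, 1e6)
        censor_time = rng.uniform(0.0, x / rate)
        time = np.minimum(event_time, censor_time)
        event = (event_time <= censor_time).astype(int)
    else:
        time = event_time
        event = np.ones(n, dtype=int)
    time = np.maximum(time, 1e-9)

    data = {"time": time, "event": event,
            "group": np.where(high, "high", "low"),
            "expression": expression}
    if with_covariates:
        data["stage"] = rng.choice(["I", "II", "III", "IV"], size=n)
        data["gender"] = rng.choice(["F", "M"], size=n)
        data["smoking"] = rng.choice(["never", "ever"], size=n)
    df = pd.DataFrame(data, index=[f"P{k:05d}" for k in range(n)])
    return SurvivalCohort(df)
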