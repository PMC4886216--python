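"""Synthetic regeneration time-course generator with planted ground truth.

Emulates the statistical structure of a cryoinjury time-course experiment:
7 condition groups (control, 4 hpi, 1/3/7/14/90 dpi) x 3 replicates, a
majority of null genes, injury-responsive genes whose effects are largest
early and vanish by 90 dpi, K planted co-expression modules driven by latent
factors, a minority of planted high-connectivity genes, plus companion
annotation / orthology / miR-target tables with known enrichment structure.

Generative model
----------------
Expression of gene g in sample s is

    x_gs = baseline_g + a_g * L_{m(g)}(s) [+ b_g * L_{m'(g)}(s)]
           + delta_g(group(s)) + eps_gs

where L_m are per-sample latent factors (standardised i.i.d. Gaussian, one
per module), a_g the module loading chosen so that two ordinary members
correlate at ``within_module_correlation``, delta_g the injury-response
group-mean shift, and eps white noise. Planted hubs carry a secondary
loading b_g on a second module and a reduced private-noise scale, so their
incident edge weights exceed those of ordinary members — the signature the
permutation hub test is designed to detect.

The injury response of gene g is

    delta_g(group) = sign_g * d_g * sd_g * effect_decay(group) ** gamma_g

with d_g the standardised effect size (in units of the gene's within-group
standard deviation sd_g), gamma_g >= 0 a response-speed exponent (shared by
the members of a module, drawn per gene in the background) and sign_g
shared within a module. Standardising the effect keeps responsive
background genes detectable without letting the common decay shape turn
them into one large spurious co-expression blob, and the per-module speed
exponents keep distinct modules' responses from collapsing onto a single
trajectory — each module peaks early but relaxes at its own rate, the way
successive regeneration programmes do.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import AnnotationTable, ExpressionMatrix

__all__ = [
    "DEFAULT_GROUPS",
    "DEFAULT_EFFECT_DECAY",
    "SimulationConfig",
    "SyntheticTruth",
    "MiRConfig",
    "simulate_timecourse",
    "simulate_annotations",
    "simulate_crossspecies",
]

DEFAULT_GROUPS: tuple[str, ...] = (
    "control", "4hpi", "1dpi", "3dpi", "7dpi", "14dpi", "90dpi",
)

#: Injury-effect multiplier per group: maximal immediately after injury,
#: decaying monotonically, zero in fully regenerated 90 dpi hearts.
DEFAULT_EFFECT_DECAY: dict[str, float] = {
    "control": 0.0,
    "4hpi": 1.0,
    "1dpi": 1.0,
    "3dpi": 0.95,
    "7dpi": 0.85,
    "14dpi": 0.75,
    "90dpi": 0.0,
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


@dataclass
class SimulationConfig:
    """Parameters of the synthetic time course.

    Defaults give a 2,000-gene, 5-module (60 genes each), 21-sample dataset:
    large enough to exercise every pipeline stage, small enough for
    seconds-scale runs.
    """

    n_genes: int = 2000
    n_modules: int = 5
    module_sizes: tuple[int, ...] | None = None  # default: 60 per module
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_replicates: int = 3
    de_fraction: float = 0.2
    effect_size: float = 2.6  # standardised (units of within-group sd)
    response_speed_range: tuple[float, float] = (0.8, 1.25)
    effect_decay: Mapping[str, float] | None = None
    within_module_correlation: float = 0.85
    noise_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    n_planted_hubs: int = 20
    hub_noise_scale: float = 0.1
    hub_secondary_loading: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            self.module_sizes = tuple([60] * self.n_modules)
        else:
            self.module_sizes = tuple(int(s) for s in self.module_sizes)
            if len(self.module_sizes) != self.n_modules:
                raise ConfigurationError(
                    f"module_sizes has {len(self.module_sizes)} entries for "
                    f"{self.n_modules} modules"
                )
        if self.effect_decay is None:
            if set(self.groups) != set(DEFAULT_GROUPS):
                raise ConfigurationError(
                    "effect_decay must be given explicitly for non-default groups"
                )
            self.effect_decay = dict(DEFAULT_EFFECT_DECAY)
        else:
            self.effect_decay = dict(self.effect_decay)
        self.validate()

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_genes:
            raise ConfigurationError(
                f"module_sizes sum to {sum(self.module_sizes)} > n_genes={self.n_genes}"
            )
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ConfigurationError("de_fraction must lie in [0, 1]")
        if not 0.0 < self.within_module_correlation < 1.0:
            raise ConfigurationError("within_module_correlation must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        lo, hi = self.response_speed_range
        if not 0 < lo <= hi:
            raise ConfigurationError("response_speed_range must satisfy 0 < lo <= hi")
        if self.n_replicates < 1:
            raise ConfigurationError("need at least one replicate per group")
        missing = set(self.groups) - set(self.effect_decay)
        if missing:
            raise ConfigurationError(f"effect_decay missing groups: {sorted(missing)}")
        injured = [g for g in self.groups if g not in ("control",)]
        mult = [self.effect_decay[g] for g in injured]
        if any(m < 0 for m in mult):
            raise ConfigurationError("effect multipliers must be non-negative")
        if any(b > a + 1e-12 for a, b in zip(mult, mult[1:])):
            raise ConfigurationError(
                "effect multipliers must be non-increasing from 4hpi onwards"
            )
        if "4hpi" in self.effect_decay and "90dpi" in self.effect_decay:
            if self.effect_decay["90dpi"] > 0.1 * self.effect_decay["4hpi"] + 1e-12:
                raise ConfigurationError(
                    "90dpi effect must be at most 10% of the 4hpi effect"
                )
        if self.n_planted_hubs > sum(self.module_sizes):
            raise ConfigurationError("more planted hubs than module genes")

    @property
    def sample_ids(self) -> list[str]:
        return [f"{g}_{r}" for g in self.groups for r in range(1, self.n_replicates + 1)]

    def sample_metadata(self) -> pd.DataFrame:
        rows = [
            {"sample": f"{g}_{r}", "group": g, "replicate": r}
            for g in self.groups
            for r in range(1, self.n_replicates + 1)
        ]
        return pd.DataFrame(rows).set_index("sample")


@dataclass
class SyntheticTruth:
    """Planted structure of one simulated dataset.

    ``module_of`` maps gene -> module id (0 = background), ``trajectories``
    holds the per-group injury effect of each responsive gene, and
    ``latent_trajectories`` the per-sample latent factor of each module
    (the recovery target for module eigengenes).
    """

    module_of: dict[str, int]
    is_de: dict[str, bool]
    trajectories: dict[str, dict[str, float]]
    is_hub: dict[str, bool]
    latent_trajectories: dict[int, list[float]]
    sample_ids: list[str]
    config: SimulationConfig | None = None

    @property
    def genes(self) -> list[str]:
        return list(self.module_of)

    def module_members(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    @property
    def modules(self) -> list[int]:
        return sorted({m for m in self.module_of.values() if m != 0})

    @property
    def hubs(self) -> list[str]:
        return [g for g, h in self.is_hub.items() if h]

    @property
    def de_genes(self) -> list[str]:
        return [g for g, d in self.is_de.items() if d]

    def validate(self) -> None:
        for g in self.hubs:
            if self.module_of[g] == 0:
                raise ValueError(f"planted hub {g} is not in a planted module")
        for g, de in self.is_de.items():
            traj = self.trajectories.get(g, {})
            if not de and any(v != 0 for v in traj.values()):
                raise ValueError(f"non-responsive gene {g} has a nonzero trajectory")

    def to_json(self, path) -> None:
        payload = {
            "module_of": self.module_of,
            "is_de": self.is_de,
            "trajectories": self.trajectories,
            "is_hub": self.is_hub,
            "latent_trajectories": {str(k): v for k, v in self.latent_trajectories.items()},
            "sample_ids": self.sample_ids,
            "config": asdict(self.config) if self.config is not None else None,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        cfg = d.get("config")
        if cfg is not None:
            cfg["module_sizes"] = tuple(cfg["module_sizes"]) if cfg["module_sizes"] else None
            cfg["groups"] = tuple(cfg["groups"])
            cfg = SimulationConfig(**cfg)
        return cls(
            module_of=d["module_of"],
            is_de=d["is_de"],
            trajectories=d["trajectories"],
            is_hub=d["is_hub"],
            latent_trajectories={int(k): v for k, v in d["latent_trajectories"].items()},
            sample_ids=d["sample_ids"],
            config=cfg,
        )


def _gene_ids(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"g{str(i).zfill(width)}" for i in range(1, n + 1)]


def simulate_timecourse(config: SimulationConfig) -> tuple[ExpressionMatrix, SyntheticTruth]:
    """Simulate a log2 expression time course with planted structure.

    Deterministic given ``config`` (including its seed). Returns the
    expression matrix and the planted truth.

    Notes
    -----
    When ``de_fraction > 0`` every planted-module member is
    injury-responsive (modules emulate coherent regeneration programmes and
    must survive injury-based gene selection); additional background genes
    are made responsive until the requested fraction is reached. When
    ``de_fraction == 0`` no gene responds — the fully null configuration
    used for calibration.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    genes = _gene_ids(cfg.n_genes)
    samples = cfg.sample_ids
    n_s = len(samples)
    group_of_sample = np.array(
        [g for g in cfg.groups for _ in range(cfg.n_replicates)]
    )

    # module membership: first genes are module members, rest background
    module_of = dict.fromkeys(genes, 0)
    pos = 0
    members_by_module: dict[int, list[str]] = {}
    for m, size in enumerate(cfg.module_sizes, start=1):
        members_by_module[m] = genes[pos : pos + size]
        for g in members_by_module[m]:
            module_of[g] = m
        pos += size
    n_module_genes = pos

    # planted hubs: distributed round-robin over modules, first members
    is_hub = dict.fromkeys(genes, False)
    if cfg.n_planted_hubs and cfg.n_modules:
        per_module = np.zeros(cfg.n_modules, dtype=int)
        for h in range(cfg.n_planted_hubs):
            per_module[h % cfg.n_modules] += 1
        for m in range(1, cfg.n_modules + 1):
            take = min(per_module[m - 1], len(members_by_module[m]))
            for g in members_by_module[m][:take]:
                is_hub[g] = True

    # per-gene within-group sd implied by the factor model (used to put
    # standardised effects on the intensity scale; hubs use the ordinary-
    # member sd so their response matches their module's)
    r = cfg.within_module_correlation
    loading = cfg.noise_sd * np.sqrt(r / (1.0 - r))
    member_sd = float(np.sqrt(loading**2 + cfg.noise_sd**2))

    def within_sd(g: str) -> float:
        return member_sd if module_of[g] else cfg.noise_sd

    # injury-responsive genes and their group-mean trajectories
    is_de = dict.fromkeys(genes, False)
    trajectories = {g: {grp: 0.0 for grp in cfg.groups} for g in genes}
    module_sign = {
        m: float(rng.choice([-1.0, 1.0])) for m in range(1, cfg.n_modules + 1)
    }
    lo, hi = cfg.response_speed_range
    module_gamma = {
        m: float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        for m in range(1, cfg.n_modules + 1)
    }
    n_de = int(round(cfg.de_fraction * cfg.n_genes))
    if n_de > 0:
        de_genes = list(genes[:n_module_genes])
        n_extra = max(0, n_de - n_module_genes)
        background = genes[n_module_genes:]
        if n_extra:
            extra = rng.choice(background, size=min(n_extra, len(background)), replace=False)
            de_genes.extend(extra.tolist())
        for g in de_genes:
            is_de[g] = True
            m = module_of[g]
            sign = module_sign[m] if m else float(rng.choice([-1.0, 1.0]))
            gamma = module_gamma[m] if m else float(
                np.exp(rng.uniform(np.log(lo), np.log(hi)))
            )
            magnitude = cfg.effect_size * rng.uniform(0.9, 1.1) * within_sd(g)
            for grp in cfg.groups:
                trajectories[g][grp] = sign * magnitude * cfg.effect_decay[grp] ** gamma

    # latent per-sample factors, standardised so loadings translate exactly
    # into correlations; when modules carry an injury response, each latent
    # is orthogonalised against its module's response profile so the latent
    # captures co-expression beyond the mean time course (otherwise chance
    # latent/profile alignment would make whole modules coherently stronger
    # or weaker than their peers)
    latents = np.zeros((cfg.n_modules, n_s))
    if cfg.n_modules:
        raw = rng.standard_normal((cfg.n_modules, n_s))
        injured = np.array(
            [cfg.effect_decay[grp] > 0 for grp in group_of_sample], dtype=float
        )
        basis_cols = [np.ones(n_s)]
        if n_de > 0:
            basis_cols.append(injured)
            for m in range(1, cfg.n_modules + 1):
                basis_cols.append(
                    np.array(
                        [cfg.effect_decay[grp] ** module_gamma[m] for grp in group_of_sample]
                    )
                )
        for m in range(1, cfg.n_modules + 1):
            # each latent is orthogonal to the mean, the injury contrast,
            # every module's response profile and the previous latents:
            # latents are distinct co-expression programmes, and chance
            # alignment between them (sd ~ 1/sqrt(n_samples)) would couple
            # whole module pairs
            basis = np.column_stack(basis_cols)
            q, _ = np.linalg.qr(basis)
            v = raw[m - 1]
            v = v - q @ (q.T @ v)
            sd = v.std()
            latents[m - 1] = v / sd if sd > 0 else v
            basis_cols.append(latents[m - 1])

    # assemble the matrix
    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=cfg.n_genes)
    X = np.tile(baseline[:, None], (1, n_s))

    group_index = {grp: np.flatnonzero(group_of_sample == grp) for grp in cfg.groups}
    noise = rng.standard_normal((cfg.n_genes, n_s))
    for gi, g in enumerate(genes):
        m = module_of[g]
        eps_scale = cfg.noise_sd
        if m:
            X[gi] += loading * latents[m - 1]
            if is_hub[g]:
                eps_scale = cfg.noise_sd * cfg.hub_noise_scale
                if cfg.n_modules > 1:
                    secondary = m % cfg.n_modules  # next module, wrapping
                    X[gi] += cfg.hub_secondary_loading * loading * latents[secondary]
        if is_de[g]:
            for grp, idx in group_index.items():
                X[gi, idx] += trajectories[g][grp]
        X[gi] += eps_scale * noise[gi]

    values = pd.DataFrame(X, index=genes, columns=samples)
    expr = ExpressionMatrix(values, cfg.sample_metadata())
    truth = SyntheticTruth(
        module_of=module_of,
        is_de=is_de,
        trajectories={g: t for g, t in trajectories.items() if is_de[g]},
        is_hub=is_hub,
        latent_trajectories={m: latents[m - 1].tolist() for m in range(1, cfg.n_modules + 1)},
        sample_ids=list(samples),
        config=cfg,
    )
    truth.validate()
    return expr, truth


def simulate_annotations(
    truth: SyntheticTruth,
    n_terms: int = 100,
    enrichment_odds: float = 5.0,
    term_size_range: tuple[int, int] = (10, 40),
    seed: int = 0,
) -> AnnotationTable:
    """Generate a GMT-style annotation table concentrated within modules.

    Each term designates one planted module (cycling through modules) and
    draws its genes without replacement with sampling odds
    ``enrichment_odds`` : 1 in favour of that module's members.
    ``enrichment_odds=1`` gives uniformly random terms (the enrichment null);
    ``numpy.inf`` draws exclusively from the module while it has genes left.
    """
    if n_terms < 1:
        raise ConfigurationError("n_terms must be >= 1")
    if not truth.modules:
        raise ConfigurationError("truth contains no planted modules")
    if enrichment_odds < 1:
        raise ConfigurationError("enrichment_odds must be >= 1")
    rng = np.random.default_rng(seed)
    genes = np.array(truth.genes)
    modules = truth.modules

    terms: dict[str, tuple[str, ...]] = {}
    descriptions: dict[str, str] = {}
    for t in range(n_terms):
        module = modules[t % len(modules)]
        in_module = np.array([truth.module_of[g] == module for g in genes])
        lo, hi = term_size_range
        size = int(rng.integers(lo, hi + 1)) if hi > lo else lo
        size = min(size, len(genes))
        if np.isinf(enrichment_odds):
            members = genes[in_module]
            take = min(size, len(members))
            chosen = rng.choice(members, size=take, replace=False).tolist()
            if take < size:
                others = genes[~in_module]
                chosen.extend(rng.choice(others, size=size - take, replace=False).tolist())
        else:
            w = np.where(in_module, float(enrichment_odds), 1.0)
            chosen = rng.choice(genes, size=size, replace=False, p=w / w.sum()).tolist()
        name = f"T{t + 1:04d}"
        terms[name] = tuple(sorted(chosen))
        descriptions[name] = f"synthetic term enriched toward module {module}"
    return AnnotationTable(terms, descriptions)


DEFAULT_ORTHOLOG_RATES: dict[str, tuple[float, float]] = {
    # (rate for planted hubs, rate for other genes); hub rates mirror the
    # conservation levels typical of central co-expression genes
    "human": (0.78, 0.50),
    "mouse": (0.79, 0.50),
    "rat": (0.78, 0.50),
}

_SPECIES_PREFIX = {"human": "HS", "mouse": "MM", "rat": "RN"}

DEFAULT_MIRS = ("hsa-miR-590-3p", "hsa-miR-1", "hsa-miR-195", "hsa-miR-199a")


@dataclass
class MiRConfig:
    """How many miR-target rows to draw per species and evidence class."""

    counts: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: {"human": (2, 18), "mouse": (0, 120), "rat": (0, 100)}
    )  # species -> (n_validated, n_predicted) targeting hub orthologs
    mirs: tuple[str, ...] = DEFAULT_MIRS
    n_decoy: int = 20  # extra rows targeting non-hub orthologs


def simulate_crossspecies(
    truth: SyntheticTruth,
    ortholog_rates: Mapping[str, tuple[float, float]] | None = None,
    mir_config: MiRConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate orthology and miR-target tables with hub-biased conservation.

    Each gene gets an ortholog in each species with probability
    ``hub_rate`` if it is a planted hub and ``other_rate`` otherwise.
    The miR-target table connects named miRs to hub orthologs (plus decoy
    rows to non-hub orthologs so joins must actually filter).

    Returns (orthology, mir_targets): headered DataFrames with columns
    (gene, species, ortholog, source) and (mir, target, species, evidence).
    """
    rates = dict(ortholog_rates if ortholog_rates is not None else DEFAULT_ORTHOLOG_RATES)
    for sp, (rh, rn) in rates.items():
        if sp not in _SPECIES_PREFIX:
            raise ConfigurationError(f"unknown species label: {sp!r}")
        if not (0 <= rh <= 1 and 0 <= rn <= 1):
            raise ConfigurationError("ortholog rates must lie in [0, 1]")
    mir_cfg = mir_config if mir_config is not None else MiRConfig()
    for sp in mir_cfg.counts:
        if sp not in _SPECIES_PREFIX:
            raise ConfigurationError(f"unknown species label in mir_config: {sp!r}")
    rng = np.random.default_rng(seed)

    genes = truth.genes
    hub_flags = np.array([truth.is_hub[g] for g in genes])
    sources = ("homologene", "zfin", "blast")

    frames = []
    ortholog_of: dict[tuple[str, str], str] = {}
    gene_arr = np.array(genes)
    for sp in sorted(rates):
        rate_hub, rate_other = rates[sp]
        p = np.where(hub_flags, rate_hub, rate_other)
        has = rng.random(len(genes)) < p
        src = rng.choice(sources, size=len(genes))
        prefix = _SPECIES_PREFIX[sp]
        kept = gene_arr[has]
        orths = np.char.add(f"{prefix}:", np.char.upper(kept.astype(str)))
        ortholog_of.update({(g, sp): o for g, o in zip(kept, orths)})
        frames.append(
            pd.DataFrame(
                {"gene": kept, "species": sp, "ortholog": orths, "source": src[has]}
            )
        )
    orthology = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["gene", "species", "ortholog", "source"])
    )

    mir_rows = []
    for sp in sorted(mir_cfg.counts):
        n_val, n_pred = mir_cfg.counts[sp]
        hub_orth = [(g, o) for (g, s), o in ortholog_of.items() if s == sp and truth.is_hub[g]]
        nonhub_orth = [(g, o) for (g, s), o in ortholog_of.items() if s == sp and not truth.is_hub[g]]
        pairs = [(mir, g, o) for mir in mir_cfg.mirs for g, o in hub_orth]
        for n, evidence in ((n_val, "validated"), (n_pred, "predicted")):
            if n <= 0 or not pairs:
                continue
            take = min(n, len(pairs))
            idx = rng.choice(len(pairs), size=take, replace=False)
            for i in idx:
                mir, g, o = pairs[i]
                mir_rows.append(
                    {"mir": mir, "target": o, "species": sp, "evidence": evidence}
                )
        if mir_cfg.n_decoy and nonhub_orth:
            take = min(mir_cfg.n_decoy, len(nonhub_orth))
            idx = rng.choice(len(nonhub_orth), size=take, replace=False)
            for i in idx:
                g, o = nonhub_orth[i]
                mir = mir_cfg.mirs[int(rng.integers(len(mir_cfg.mirs)))]
                mir_rows.append(
                    {"mir": mir, "target": o, "species": sp, "evidence": "predicted"}
                )
    mir_targets = pd.DataFrame(mir_rows, columns=["mir", "target", "species", "evidence"])
    return orthology, mir_targets
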