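"""Synthetic scenario generator with planted ground truth.

Emulates a nested sampling design (plots in fields in sites) over a taxa pool
with guild labels, an interaction network with planted block structure and
typed edges, lognormal read counts whose detection probability declines with
land-use intensity, and management criteria correlated with a latent
intensity axis.  Everything is deterministic given ``ScenarioConfig.seed``.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

GUILDS = (
    "bacteria_decomposer",
    "fungi_saprotroph",
    "detritivore",
    "root_herbivore",
    "parasite",
    "predator",
    "other_basal",
    "other_consumer",
)

#: guilds treated as micro-organisms (broad geographic distribution assumed)
MICRO_GUILDS = frozenset({"bacteria_decomposer", "fungi_saprotroph"})

HABITAT_LAYERS = ("surface", "0-10cm", ">10cm")

DEFAULT_GUILD_PROPORTIONS: dict[str, float] = {
    "bacteria_decomposer": 0.25,
    "fungi_saprotroph": 0.20,
    "detritivore": 0.12,
    "root_herbivore": 0.10,
    "parasite": 0.10,
    "predator": 0.10,
    "other_basal": 0.08,
    "other_consumer": 0.05,
}

# fixed offsets added to the scenario seed so each stage has its own stream
# and adding taxa does not reshuffle field-level draws
_STREAM_TAXA = 11
_STREAM_KB = 23
_STREAM_OBS = 37
_STREAM_CRITERIA = 53


def _substream(seed: int, offset: int) -> np.random.Generator:
    return np.random.default_rng(int(seed) + offset)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic scenario."""

    n_sites: int = 4
    fields_per_site: int = 4
    plots_per_field: int = 4
    n_replicates: int = 4
    n_taxa: int = 120
    n_groups: int = 4
    pi_within: float = 0.55
    pi_between: float = 0.05
    guild_proportions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GUILD_PROPORTIONS)
    )
    parasitic_edge_prob: float = 0.8
    symbiotic_edge_prob: float = 0.05
    detection_prob: float = 0.9
    replicate_detection_prob: float = 0.8
    detection_decay: float = 0.0
    sensitive_guilds: tuple[str, ...] = ("parasite", "fungi_saprotroph")
    exotic_fraction: float = 0.05
    site_sd: float = 0.3
    residual_sd: float = 0.2
    n_criteria: int = 6
    criteria_noise_sd: float = 0.2
    lui_slope_per_metric: Mapping[str, float] = field(default_factory=dict)
    guild_aligned_groups: bool = False
    read_mu: float = 5.0
    read_sigma: float = 1.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_sites", "fields_per_site", "plots_per_field",
                     "n_replicates", "n_taxa", "n_groups", "n_criteria"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.n_groups > self.n_taxa:
            raise ValueError("n_groups cannot exceed n_taxa")
        for name in ("pi_within", "pi_between", "parasitic_edge_prob",
                     "symbiotic_edge_prob", "detection_prob",
                     "replicate_detection_prob", "exotic_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1]")
        for name in ("site_sd", "residual_sd", "criteria_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        props = dict(self.guild_proportions)
        unknown = set(props) - set(GUILDS)
        if unknown:
            raise ValueError(f"unknown guilds: {sorted(unknown)}")
        if any(p < 0 for p in props.values()):
            raise ValueError("guild proportions must be non-negative")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("guild_proportions must sum to 1 within 1e-9")

    @property
    def n_fields(self) -> int:
        return self.n_sites * self.fields_per_site


@dataclass
class GroundTruth:
    """Planted quantities the pipeline must recover, never read by it."""

    membership: dict[str, int]
    true_lui: dict[str, float]
    true_slopes: dict[str, float]

    def to_json(self) -> str:
        return json.dumps(asdict(self), sort_keys=True, indent=1)


def generate_taxa_pool(config: ScenarioConfig):
    """Draw the taxa pool: lineage, guild/habitat annotations and planted groups.

    Returns ``(taxonomy, annotations, truth)`` where taxonomy has columns
    taxon_id/phylum/family/genus/species, annotations has taxon_id/guild/
    habitat_layers/geographic_tags/is_microorganism, and ``truth`` carries the
    planted group membership (LUI and slopes are filled by later stages).
    """
    config.validate()
    rng = _substream(config.seed, _STREAM_TAXA)
    n = config.n_taxa
    guild_names = list(config.guild_proportions)
    probs = np.array([config.guild_proportions[g] for g in guild_names])
    guilds = rng.choice(guild_names, size=n, p=probs / probs.sum())
    if config.guild_aligned_groups:
        # groups follow guilds (guild g -> group g mod Q): taxon loss in the
        # sensitive guilds can then empty whole groups, planting a clean
        # group-richness decline along the intensity gradient
        guild_idx = {g: k for k, g in enumerate(GUILDS)}
        membership = np.array(
            [guild_idx[g] % config.n_groups for g in guilds])
    else:
        membership = rng.integers(0, config.n_groups, size=n)

    taxon_ids = [f"t{i + 1:04d}" for i in range(n)]
    rows = []
    # nest taxa into families of ~4 and genera of ~2 inside each guild so the
    # family-generalization machinery has something to expand
    per_guild_counter: dict[str, int] = {}
    for tid, g in zip(taxon_ids, guilds):
        k = per_guild_counter.get(g, 0)
        per_guild_counter[g] = k + 1
        phylum = f"P_{g}"
        fam = f"F_{g}_{k // 4}"
        gen = f"G_{g}_{k // 2}"
        rows.append((tid, phylum, fam, gen, f"{gen}_sp{k}"))
    taxonomy = pd.DataFrame(
        rows, columns=["taxon_id", "phylum", "family", "genus", "species"]
    )

    n_layers = rng.integers(1, len(HABITAT_LAYERS) + 1, size=n)
    layer_sets = []
    for k in n_layers:
        chosen = rng.choice(len(HABITAT_LAYERS), size=k, replace=False)
        layer_sets.append("|".join(HABITAT_LAYERS[i] for i in sorted(chosen)))
    is_micro = np.isin(guilds, list(MICRO_GUILDS))
    exotic = rng.random(n) < config.exotic_fraction
    geo = np.where(exotic & ~is_micro, "tropical", "temperate_europe")
    annotations = pd.DataFrame(
        {
            "taxon_id": taxon_ids,
            "guild": guilds,
            "habitat_layers": layer_sets,
            "geographic_tags": geo,
            "is_microorganism": is_micro,
        }
    )
    truth = GroundTruth(
        membership={t: int(m) for t, m in zip(taxon_ids, membership)},
        true_lui={},
        true_slopes=dict(config.lui_slope_per_metric),
    )
    return taxonomy, annotations, truth


def generate_interaction_kb(
    taxonomy: pd.DataFrame,
    annotations: pd.DataFrame,
    truth: GroundTruth,
    config: ScenarioConfig,
) -> pd.DataFrame:
    """Sample directed resource->consumer records with planted block structure.

    P(i -> j) is ``pi_within`` when i and j share a planted group and
    ``pi_between`` otherwise; no self-loops.  Edges whose consumer belongs to
    the parasite guild are typed parasitism with probability
    ``parasitic_edge_prob``; other edges are symbiosis with probability
    ``symbiotic_edge_prob``; everything else is predation.
    """
    config.validate()
    taxa = list(taxonomy["taxon_id"])
    missing = [t for t in taxa if t not in truth.membership]
    if missing:
        raise ValueError(f"membership missing for taxa: {missing[:5]}")
    rng = _substream(config.seed, _STREAM_KB)
    n = len(taxa)
    mem = np.array([truth.membership[t] for t in taxa])
    same = mem[:, None] == mem[None, :]
    p = np.where(same, config.pi_within, config.pi_between)
    np.fill_diagonal(p, 0.0)
    adj = rng.random((n, n)) < p

    guild_of = dict(zip(annotations["taxon_id"], annotations["guild"]))
    res_idx, con_idx = np.nonzero(adj)
    u_type = rng.random(res_idx.size)
    records = []
    for (i, j, u) in zip(res_idx, con_idx, u_type):
        consumer = taxa[j]
        if guild_of[consumer] == "parasite":
            etype = "parasitism" if u < config.parasitic_edge_prob else "predation"
        else:
            etype = "symbiosis" if u < config.symbiotic_edge_prob else "predation"
        records.append((taxa[i], consumer, etype, "species", "synthetic"))
    return pd.DataFrame(
        records,
        columns=["resource", "consumer", "type", "evidence_rank", "source"],
    )


def _field_layout(config: ScenarioConfig):
    """Site/field/plot identifiers in a fixed order."""
    sites, fields, plots = [], [], []
    for s in range(config.n_sites):
        site_id = f"site{s + 1}"
        sites.append(site_id)
        for f in range(config.fields_per_site):
            field_id = f"{site_id}_f{f + 1}"
            fields.append((site_id, field_id))
            for p in range(config.plots_per_field):
                plots.append((site_id, field_id, f"{field_id}_p{p + 1}"))
    return sites, fields, plots


def generate_field_observations(
    taxonomy: pd.DataFrame,
    annotations: pd.DataFrame,
    config: ScenarioConfig,
    truth: GroundTruth,
):
    """Simulate plot x replicate x taxon detections with read counts.

    Per-field LUI values sit on an evenly spaced gradient (sites ordered along
    it) plus a Gaussian site offset.  The detection probability of taxa in
    ``sensitive_guilds`` decays exponentially with LUI at rate
    ``detection_decay``, which plants negative metric-LUI slopes downstream.
    Read counts are lognormal, rounded up, so detected taxa always have >= 1
    read.  Fills ``truth.true_lui`` in place.
    """
    config.validate()
    rng = _substream(config.seed, _STREAM_OBS)
    sites, fields, plots = _field_layout(config)
    n_fields = len(fields)
    base = np.linspace(-2.0, 2.0, n_fields) if n_fields > 1 else np.array([0.0])
    site_offset = {s: rng.normal(0.0, config.site_sd) for s in sites}
    # interleave the gradient across sites (field j of site s takes position
    # j * n_sites + s) so LUI varies within every site and the site random
    # intercept stays identifiable
    lui = {}
    for k, (sid, fid) in enumerate(fields):
        s = sites.index(sid)
        j = k % config.fields_per_site
        lui[fid] = float(base[j * config.n_sites + s] + site_offset[sid])
    truth.true_lui = lui
    lui_min = min(lui.values())

    taxa = list(taxonomy["taxon_id"])
    guild_of = dict(zip(annotations["taxon_id"], annotations["guild"]))
    sensitive = np.array(
        [guild_of[t] in set(config.sensitive_guilds) for t in taxa]
    )

    rows = []
    for sid, fid, pid in plots:
        decay = math.exp(-config.detection_decay * max(lui[fid] - lui_min, 0.0))
        p_det = np.where(
            sensitive, config.detection_prob * decay, config.detection_prob
        )
        detected = rng.random(len(taxa)) < p_det
        for t_idx in np.nonzero(detected)[0]:
            hits = rng.random(config.n_replicates) < config.replicate_detection_prob
            for r in np.nonzero(hits)[0]:
                reads = int(
                    math.ceil(rng.lognormal(config.read_mu, config.read_sigma))
                )
                rows.append((pid, int(r + 1), taxa[t_idx], reads))
    observations = pd.DataFrame(
        rows, columns=["plot_id", "replicate", "taxon_id", "reads"]
    )
    design = pd.DataFrame(plots, columns=["site_id", "field_id", "plot_id"])
    return observations, design


# loading pattern cycled to fill n_criteria; some negative on purpose so the
# sign-orientation of the recovered axis is exercised
_CRITERION_LOADINGS = [
    ("mineral_n", 1.0),
    ("tillage_depth", 0.8),
    ("crop_protection", 0.9),
    ("residue_return", -0.7),
    ("tillage_frequency", 0.6),
    ("legume_fixation", -0.5),
]


def generate_management_criteria(
    config: ScenarioConfig, truth: GroundTruth
) -> pd.DataFrame:
    """Field x criterion table; each criterion = loading * true LUI + noise.

    Noise SD is ``criteria_noise_sd`` times the signal SD of that criterion,
    so 0 gives perfect collinearity with the latent axis.
    """
    config.validate()
    if not truth.true_lui:
        raise ValueError("truth.true_lui empty: generate observations first")
    rng = _substream(config.seed, _STREAM_CRITERIA)
    fields = sorted(truth.true_lui)
    lui = np.array([truth.true_lui[f] for f in fields])
    signal_sd = lui.std(ddof=0) if len(fields) > 1 else 1.0
    data = {}
    for k in range(config.n_criteria):
        name, a = _CRITERION_LOADINGS[k % len(_CRITERION_LOADINGS)]
        if k >= len(_CRITERION_LOADINGS):
            name = f"{name}_{k // len(_CRITERION_LOADINGS) + 1}"
        noise = rng.normal(0.0, config.criteria_noise_sd * abs(a) * signal_sd,
                           size=len(fields))
        data[name] = a * lui + noise
    out = pd.DataFrame(data, index=pd.Index(fields, name="field_id"))
    constant = [c for c in out.columns if out[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping zero-variance criteria: {constant}")
        out = out.drop(columns=constant)
    return out


@dataclass
class Scenario:
    """All generated tables plus the ground truth sidecar."""

    config: ScenarioConfig
    taxonomy: pd.DataFrame
    annotations: pd.DataFrame
    interactions: pd.DataFrame
    observations: pd.DataFrame
    design: pd.DataFrame
    criteria: pd.DataFrame
    truth: GroundTruth


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Run all four generators in order under one seed."""
    taxonomy, annotations, truth = generate_taxa_pool(config)
    interactions = generate_interaction_kb(taxonomy, annotations, truth, config)
    observations, design = generate_field_observations(
        taxonomy, annotations, config, truth
    )
    criteria = generate_management_criteria(config, truth)
    return Scenario(
        config, taxonomy, annotations, interactions, observations, design,
        criteria, truth,
    )


def write_scenario(scenario: Scenario, outdir: str | Path) -> dict[str, Path]:
    """Write all tables as TSV plus the ground-truth JSON sidecar."""
    from .io import write_tsv

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in ("taxonomy", "annotations", "interactions", "observations",
                 "design"):
        paths[name] = outdir / f"{name}.tsv"
        write_tsv(getattr(scenario, name), paths[name])
    paths["criteria"] = outdir / "criteria.tsv"
    write_tsv(scenario.criteria.reset_index(), paths["criteria"])
    paths["ground_truth"] = outdir / "ground_truth.json"
    paths["ground_truth"].write_text(scenario.truth.to_json() + "\n")
    return paths
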