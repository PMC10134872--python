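"""Forward simulator of spike-in live/dead viability-PCR studies.

Generates the full observable record of a PMAxx viability experiment --
plate-style qPCR tables, MetaPhlAn-style relative-abundance tables, read
accounting and study metadata -- from a ground-truth community in which every
taxon carries separate live and dead (exposed-DNA) 16S copy pools. The
generative chain is:

    community (live/dead copies per taxon, host cells)
      -> treatment maps (osmotic lysis + PMAxx; freeze-thaw; their composite)
      -> qPCR readout   (standard-curve line + Gaussian Ct noise, censored
                         at the cycle cap)
      -> sequencing     (multinomial reads weighted by copies x genome
                         length x extraction efficiency; host reads weighted
                         by host genome mass)

Because the ground truth (per-taxon live fractions, treatment retentions,
freeze-thaw survivals, true loads) is recorded alongside the observables,
every downstream estimator in the analysis modules can be checked for
parameter recovery without any external data.

The default study design is 3 hosts x 3 groups (control, lyPMAxx,
frozen+lyPMAxx) x 3 technical replicates for each of saliva and feces (54
samples), with four exogenous spike-in strains (two heat-killed, two live;
one Gram+/Gram- of each) dosed at ~10% of the native load.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from typing import Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .abundance import GROUPS, SAMPLE_TYPES, ReadAccounting, SampleRecord
from .errors import InvalidConfigError, InvalidInputError
from .qpcr import MAX_CYCLES, QpcrMeasurement, StandardCurve

__all__ = [
    "TaxonSpec",
    "SyntheticCommunitySpec",
    "TreatmentEffect",
    "AssaySpec",
    "Community",
    "StudyConfig",
    "StudyData",
    "make_community",
    "apply_treatment",
    "simulate_qpcr",
    "simulate_sequencing",
    "generate_study",
    "write_study",
    "SPIKE_STRAINS",
    "mock_community_spec",
]

_PHYLUM_GRAM = {
    "Firmicutes": "positive",
    "Actinobacteria": "positive",
    "Bacteroidetes": "negative",
    "Proteobacteria": "negative",
    "Fusobacteria": "negative",
}


def _lineage(name: str, phylum: str) -> str:
    genus = name.split()[0]
    sp = name.replace(" ", "_")
    return (
        f"k__Bacteria|p__{phylum}|c__{phylum}_c|o__{phylum}_o"
        f"|f__{genus}aceae|g__{genus}|s__{sp}"
    )


@dataclass(frozen=True)
class TaxonSpec:
    """Ground-truth description of one community member."""

    name: str
    phylum: str
    gram: Literal["positive", "negative"]
    live_copies: float
    dead_copies: float
    genome_length: float = 3.0e6
    extraction_efficiency: float = 1.0
    is_spikein: bool = False

    def __post_init__(self):
        if self.live_copies < 0 or self.dead_copies < 0:
            raise InvalidInputError(f"{self.name}: copies must be nonnegative")
        if not 0.0 < self.extraction_efficiency <= 1.0:
            raise InvalidInputError(
                f"{self.name}: extraction_efficiency must be in (0, 1]"
            )
        if self.genome_length <= 0:
            raise InvalidInputError(f"{self.name}: genome_length must be positive")

    @property
    def lineage(self) -> str:
        return _lineage(self.name, self.phylum)


@dataclass(frozen=True)
class SyntheticCommunitySpec:
    """A community blueprint: taxa plus host-cell contamination."""

    taxa: tuple[TaxonSpec, ...]
    host_cell_count: float = 0.0
    host_genome_mass_weight: float = 1000.0  # human genome ~10^3 x bacterial

    def __post_init__(self):
        if not self.taxa:
            raise InvalidInputError("community spec has no taxa")
        if self.host_cell_count < 0 or self.host_genome_mass_weight < 0:
            raise InvalidInputError("host parameters must be nonnegative")
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            raise InvalidInputError("duplicate taxon names in spec")


@dataclass(frozen=True)
class TreatmentEffect:
    """Retention/survival fractions of the two bench treatments.

    ``dead_dna_retention``: fraction of exposed (dead-cell/free) DNA that
    survives PMAxx; ``live_dna_retention``: fraction of intact-cell DNA that
    remains amplifiable (PMAxx has a mild effect on live cells too);
    ``host_dna_retention``: host DNA surviving osmotic lysis + PMAxx;
    ``freezing_survival``: fraction of live cells still live after one
    freeze-thaw cycle, either a scalar or a per-taxon mapping.
    """

    dead_dna_retention: float = 0.05
    live_dna_retention: float = 0.6
    host_dna_retention: float = 5.0e-4
    freezing_survival: float | Mapping[str, float] = 0.35

    def __post_init__(self):
        for nm in ("dead_dna_retention", "live_dna_retention", "host_dna_retention"):
            v = getattr(self, nm)
            if not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"{nm} must be in [0, 1], got {v}")
        fs = self.freezing_survival
        vals = fs.values() if isinstance(fs, Mapping) else [fs]
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise InvalidInputError("freezing_survival values must be in [0, 1]")

    def survival_for(self, taxon: str) -> float:
        fs = self.freezing_survival
        if isinstance(fs, Mapping):
            if taxon not in fs:
                raise InvalidInputError(f"no freezing survival for taxon {taxon!r}")
            return fs[taxon]
        return fs


@dataclass(frozen=True)
class AssaySpec:
    """Measurement model shared by the qPCR and sequencing readouts."""

    curve: StandardCurve = field(
        default_factory=lambda: StandardCurve(slope=-3.3219280948873623, intercept=37.0)
    )
    ct_noise_sd: float = 0.15
    max_cycles: int = MAX_CYCLES
    sequencing_depth: int = 100_000
    template_fraction: float = 0.02  # 1 uL of a 50-uL eluate per sample unit
    qpcr_replicates: int = 3

    def __post_init__(self):
        if self.ct_noise_sd < 0:
            raise InvalidInputError("ct_noise_sd must be >= 0")
        if self.sequencing_depth < 1:
            raise InvalidInputError("sequencing_depth must be >= 1")
        if not 0 < self.template_fraction <= 1:
            raise InvalidInputError("template_fraction must be in (0, 1]")
        if self.qpcr_replicates < 1:
            raise InvalidInputError("qpcr_replicates must be >= 1")


@dataclass(frozen=True)
class Community:
    """Instantiated community state: per-taxon live/dead amplifiable copies
    (per sample unit) and the host DNA signal."""

    taxa: tuple[TaxonSpec, ...]
    live: np.ndarray
    dead: np.ndarray
    host_signal: float
    host_genome_mass_weight: float = 1000.0

    @property
    def amplifiable(self) -> np.ndarray:
        return self.live + self.dead

    @property
    def total_amplifiable(self) -> float:
        return float(self.amplifiable.sum())

    def taxon_index(self, name: str) -> int:
        for i, t in enumerate(self.taxa):
            if t.name == name:
                return i
        raise InvalidInputError(f"unknown taxon {name!r}")


# ---------------------------------------------------------------------------
# Core generative operations
# ---------------------------------------------------------------------------


def make_community(
    spec: SyntheticCommunitySpec,
    seed: int | np.random.SeedSequence = 0,
    *,
    variation_sigma: float = 0.0,
) -> Community:
    """Instantiate a community from its blueprint.

    With ``variation_sigma`` > 0, per-taxon copies are jittered by a
    log-normal factor (aliquot/inter-host variability); sigma 0 gives the
    exact blueprint. Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    live = np.array([t.live_copies for t in spec.taxa], dtype=float)
    dead = np.array([t.dead_copies for t in spec.taxa], dtype=float)
    if variation_sigma > 0:
        factors = rng.lognormal(0.0, variation_sigma, size=live.size)
        live, dead = live * factors, dead * factors
    return Community(
        taxa=tuple(spec.taxa),
        live=live,
        dead=dead,
        host_signal=float(spec.host_cell_count),
        host_genome_mass_weight=spec.host_genome_mass_weight,
    )


def apply_treatment(
    community: Community,
    effect: TreatmentEffect,
    mode: Literal["lyPMAxx", "freezing", "freezing_then_lyPMAxx"],
) -> Community:
    """Apply a treatment map to the community state.

    ``freezing`` moves killed live cells into the exposed/dead pool;
    ``lyPMAxx`` shrinks each pool by its retention (and host DNA by its own);
    the combined mode composes them in bench order (freeze-thaw first, then
    osmotic lysis + PMAxx). Amplifiable totals can only decrease.
    """
    if mode not in ("lyPMAxx", "freezing", "freezing_then_lyPMAxx"):
        raise InvalidInputError(f"unknown treatment mode {mode!r}")
    live, dead, host = community.live, community.dead, community.host_signal
    if mode in ("freezing", "freezing_then_lyPMAxx"):
        s = np.array([effect.survival_for(t.name) for t in community.taxa])
        killed = live * (1.0 - s)
        live, dead = live * s, dead + killed
    if mode in ("lyPMAxx", "freezing_then_lyPMAxx"):
        live = live * effect.live_dna_retention
        dead = dead * effect.dead_dna_retention
        host = host * effect.host_dna_retention
    return replace(community, live=live, dead=dead, host_signal=host)


def simulate_qpcr(
    community: Community,
    assay: AssaySpec,
    targets: Sequence[str],
    *,
    sample_id: str = "sim",
    seed: int | np.random.SeedSequence = 0,
) -> list[QpcrMeasurement]:
    """Simulate qPCR wells for the requested targets.

    Targets are taxon names, ``universal_16S`` (sum of all amplifiable
    bacterial copies) or ``host_marker``. Each replicate draws
    ``Ct = intercept + slope*log10(copies_in_reaction) + N(0, sd)``,
    censored at the cycle cap; zero template is always censored.
    """
    rng = np.random.default_rng(seed)
    out: list[QpcrMeasurement] = []
    for target in targets:
        if target == "universal_16S":
            copies_per_unit = community.total_amplifiable
        elif target == "host_marker":
            copies_per_unit = community.host_signal
        else:
            copies_per_unit = float(community.amplifiable[community.taxon_index(target)])
        copies = copies_per_unit * assay.template_fraction
        for rep in range(1, assay.qpcr_replicates + 1):
            if copies <= 0:
                out.append(QpcrMeasurement(sample_id, target, None, rep, censored=True))
                continue
            ct = assay.curve.ct(copies) + rng.normal(0.0, assay.ct_noise_sd)
            if ct >= assay.max_cycles or ct <= 0:
                out.append(QpcrMeasurement(sample_id, target, None, rep, censored=True))
            else:
                out.append(QpcrMeasurement(sample_id, target, float(ct), rep))
    return out


def simulate_sequencing(
    community: Community,
    assay: AssaySpec,
    *,
    sample_id: str = "sim",
    seed: int | np.random.SeedSequence = 0,
) -> tuple[pd.Series, ReadAccounting]:
    """Simulate a shotgun readout: multinomial reads over host + taxa.

    Read probabilities are proportional to DNA mass reaching the library:
    amplifiable copies x genome length x extraction efficiency per taxon, and
    host signal x host genome mass weight for the host. The returned Series
    maps lineage -> relative abundance in the taxon-profiler convention
    (read counts divided by genome length, renormalised over microbial taxa);
    spike-in reads are counted separately in the accounting.
    """
    rng = np.random.default_rng(seed)
    glen = np.array([t.genome_length for t in community.taxa])
    eff = np.array([t.extraction_efficiency for t in community.taxa])
    weights = community.amplifiable * glen * eff
    host_w = community.host_signal * community.host_genome_mass_weight
    allw = np.concatenate([[host_w], weights])
    total = allw.sum()
    if total <= 0:
        raise InvalidInputError("community has no amplifiable DNA to sequence")
    reads = rng.multinomial(assay.sequencing_depth, allw / total)
    host_reads, taxon_reads = int(reads[0]), reads[1:]
    spike_mask = np.array([t.is_spikein for t in community.taxa])
    acct = ReadAccounting(
        sample_id=sample_id,
        host_reads=host_reads,
        microbial_reads=int(taxon_reads.sum()),
        spikein_reads=int(taxon_reads[spike_mask].sum()),
    )
    depth_corrected = taxon_reads / glen
    denom = depth_corrected.sum()
    rel = depth_corrected / denom if denom > 0 else depth_corrected
    profile = pd.Series(rel, index=[t.lineage for t in community.taxa], name=sample_id)
    return profile, acct


# ---------------------------------------------------------------------------
# Study-level configuration and generation
# ---------------------------------------------------------------------------

#: Exogenous spike-in panel: two heat-killed and two live strains, one
#: Gram+/Gram- of each, dosed in fixed mutual proportions. The Gram+
#: heat-killed strain is given a very low extraction efficiency, which makes
#: it drop out of the sequencing table (a realistic lysis-bias failure mode).
SPIKE_STRAINS: tuple[dict, ...] = (
    dict(name="Escherichia coli", phylum="Proteobacteria", gram="negative",
         status="dead", genome_length=5.0e6, extraction_efficiency=0.8,
         saliva_share=0.0558, feces_share=0.0557),
    dict(name="Lactiplantibacillus plantarum", phylum="Firmicutes", gram="positive",
         status="dead", genome_length=3.3e6, extraction_efficiency=0.01,
         saliva_share=0.3718, feces_share=0.3701),
    dict(name="Enterococcus faecalis", phylum="Firmicutes", gram="positive",
         status="live", genome_length=3.2e6, extraction_efficiency=0.5,
         saliva_share=0.2659, feces_share=0.2656),
    dict(name="Salmonella enterica", phylum="Proteobacteria", gram="negative",
         status="live", genome_length=4.9e6, extraction_efficiency=0.8,
         saliva_share=0.3065, feces_share=0.3079),
)


def mock_community_spec(
    *,
    per_strain_copies: float = 2.0e8,
    host_cells: float = 2.0e5,
) -> SyntheticCommunitySpec:
    """Simple four-strain synthetic cellular community (two heat-killed, two
    live strains plus host cells), the minimal test bed for depletion
    arithmetic."""
    taxa = []
    for s in SPIKE_STRAINS:
        live = per_strain_copies if s["status"] == "live" else 0.0
        dead = per_strain_copies if s["status"] == "dead" else 0.0
        taxa.append(
            TaxonSpec(
                name=s["name"], phylum=s["phylum"], gram=s["gram"],
                live_copies=live, dead_copies=dead,
                genome_length=s["genome_length"],
                extraction_efficiency=s["extraction_efficiency"],
                is_spikein=True,
            )
        )
    return SyntheticCommunitySpec(taxa=tuple(taxa), host_cell_count=host_cells)


@dataclass(frozen=True)
class SampleTypeParams:
    """Per-sample-type generator settings (community scale and structure)."""

    unit: str
    n_core_species: int
    n_private_species: int
    load_mean: float                      # copies per unit, control condition
    load_sigma: float                     # lognormal sigma across hosts
    live_frac_beta: tuple[float, float]   # Beta(a, b) of per-taxon live fraction
    host_read_fraction: float             # pre-treatment host-read proportion
    weight_sigma: float = 2.0             # lognormal sigma of core weights
    host_weight_sigma: float = 0.7        # per-host perturbation of weights
    phylum_probs: tuple[tuple[str, float], ...] = ()
    freezing_beta: tuple[tuple[str, tuple[float, float]], ...] = ()


_DEFAULT_SALIVA = SampleTypeParams(
    unit="per_mL",
    n_core_species=102,
    n_private_species=20,
    load_mean=1.0e9,
    load_sigma=0.3,
    live_frac_beta=(6.4, 3.6),       # mean 0.64 live
    host_read_fraction=0.85,
    phylum_probs=(
        ("Firmicutes", 0.35), ("Proteobacteria", 0.25), ("Bacteroidetes", 0.15),
        ("Actinobacteria", 0.15), ("Fusobacteria", 0.10),
    ),
    # Freeze-thaw cell survival per phylum; the resulting frozen-group load
    # lands near 35% of the untreated control (most of the loss already being
    # dead cells), with Proteobacteria hit hardest.
    freezing_beta=(
        ("Proteobacteria", (6.5, 3.5)), ("Firmicutes", (9.0, 1.0)),
        ("Bacteroidetes", (9.0, 1.0)), ("Actinobacteria", (8.5, 1.5)),
        ("Fusobacteria", (8.5, 1.5)),
    ),
)

_DEFAULT_FECES = SampleTypeParams(
    unit="per_g",
    n_core_species=63,
    n_private_species=20,
    load_mean=1.0e11,
    load_sigma=0.4,
    live_frac_beta=(5.7, 4.3),       # mean 0.57 live
    host_read_fraction=0.001,
    phylum_probs=(
        ("Firmicutes", 0.45), ("Bacteroidetes", 0.35), ("Proteobacteria", 0.08),
        ("Actinobacteria", 0.10), ("Fusobacteria", 0.02),
    ),
    # Fecal cells barely survive a glycerol freeze-thaw: frozen-group loads
    # land near 6% of the untreated control, dominated by residual dead-DNA
    # signal, with Bacteroidetes/Firmicutes hit hardest and Actinobacteria
    # relatively spared.
    freezing_beta=(
        ("Bacteroidetes", (0.3, 9.7)), ("Firmicutes", (0.3, 9.7)),
        ("Proteobacteria", (1.0, 9.0)), ("Actinobacteria", (1.5, 8.5)),
        ("Fusobacteria", (0.5, 9.5)),
    ),
)


@dataclass(frozen=True)
class StudyConfig:
    """Full study-design configuration (defaults are the reference design:
    3 hosts x 3 groups x 3 replicates per sample type, ~10% spike dose)."""

    n_hosts: int = 3
    n_replicates: int = 3
    groups: tuple[str, ...] = GROUPS
    sample_types: tuple[str, ...] = SAMPLE_TYPES
    saliva: SampleTypeParams = _DEFAULT_SALIVA
    feces: SampleTypeParams = _DEFAULT_FECES
    treatment: TreatmentEffect = field(default_factory=TreatmentEffect)
    assay: AssaySpec = field(default_factory=AssaySpec)
    spike_target_fraction: float = 0.10
    replicate_jitter_sigma: float = 0.05

    def __post_init__(self):
        if self.n_hosts < 1 or self.n_replicates < 1:
            raise InvalidConfigError("n_hosts and n_replicates must be >= 1")
        unknown_g = set(self.groups) - set(GROUPS)
        if unknown_g:
            raise InvalidConfigError(f"unknown groups {sorted(unknown_g)}", "groups")
        if "control" not in self.groups:
            raise InvalidConfigError("a control group is required", "groups")
        unknown_t = set(self.sample_types) - set(SAMPLE_TYPES)
        if unknown_t:
            raise InvalidConfigError(
                f"unknown sample types {sorted(unknown_t)}", "sample_types"
            )
        if not 0.0 < self.spike_target_fraction < 1.0:
            raise InvalidConfigError(
                "spike_target_fraction must be in (0, 1)", "spike_target_fraction"
            )

    def params_for(self, sample_type: str) -> SampleTypeParams:
        return self.saliva if sample_type == "saliva" else self.feces

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        """Build a config from a plain (YAML/JSON-loaded) mapping, rejecting
        unknown keys with the offending path."""
        d = dict(d)
        kwargs: dict = {}
        for st in ("saliva", "feces"):
            if st in d:
                sub = dict(d.pop(st))
                base = _DEFAULT_SALIVA if st == "saliva" else _DEFAULT_FECES
                valid = set(SampleTypeParams.__dataclass_fields__)
                bad = set(sub) - valid
                if bad:
                    raise InvalidConfigError(f"unknown keys {sorted(bad)}", st)
                if "live_frac_beta" in sub:
                    sub["live_frac_beta"] = tuple(sub["live_frac_beta"])
                for key in ("phylum_probs", "freezing_beta"):
                    if key in sub:
                        sub[key] = tuple(
                            (k, tuple(v) if isinstance(v, (list, tuple)) else v)
                            for k, v in dict(sub[key]).items()
                        )
                kwargs[st] = replace(base, **sub)
        if "treatment" in d:
            sub = dict(d.pop("treatment"))
            bad = set(sub) - set(TreatmentEffect.__dataclass_fields__)
            if bad:
                raise InvalidConfigError(f"unknown keys {sorted(bad)}", "treatment")
            kwargs["treatment"] = TreatmentEffect(**sub)
        if "assay" in d:
            sub = dict(d.pop("assay"))
            if "curve" in sub:
                sub["curve"] = StandardCurve(**sub["curve"])
            bad = set(sub) - set(AssaySpec.__dataclass_fields__)
            if bad:
                raise InvalidConfigError(f"unknown keys {sorted(bad)}", "assay")
            kwargs["assay"] = AssaySpec(**sub)
        for key in ("groups", "sample_types"):
            if key in d:
                kwargs[key] = tuple(d.pop(key))
        valid_top = set(cls.__dataclass_fields__)
        bad = set(d) - valid_top
        if bad:
            raise InvalidConfigError(f"unknown keys {sorted(bad)}")
        kwargs.update(d)
        return cls(**kwargs)


@dataclass
class StudyData:
    """Generated study: observables plus the ground-truth ledger."""

    metadata: pd.DataFrame           # sample_id, host_id, sample_type, group, replicate
    qpcr: pd.DataFrame               # sample_id, assay, replicate, ct ('' = censored)
    standard_curve_points: pd.DataFrame
    taxon_tables: dict[str, pd.DataFrame]   # sample_type -> lineage x sample (percent)
    read_accounting: pd.DataFrame
    truth_loads: pd.DataFrame        # per-sample true amplifiable load
    truth_taxa: pd.DataFrame         # per (sample_type, taxon) ground truth
    config: StudyConfig
    seed: int

    def sample_records(self) -> list[SampleRecord]:
        return [
            SampleRecord(
                sample_id=r.sample_id, host_id=r.host_id,
                sample_type=r.sample_type, group=r.group, replicate=int(r.replicate),
            )
            for r in self.metadata.itertuples()
        ]

    def content_hash(self) -> str:
        """SHA-256 over all generated tables (determinism checks)."""
        h = hashlib.sha256()
        frames = [
            self.metadata, self.qpcr, self.standard_curve_points,
            self.read_accounting, self.truth_loads, self.truth_taxa,
            *[self.taxon_tables[k] for k in sorted(self.taxon_tables)],
        ]
        for f in frames:
            h.update(f.to_csv().encode())
        return h.hexdigest()


def _draw_phylum(rng, probs: tuple[tuple[str, float], ...]) -> str:
    names = [p[0] for p in probs]
    w = np.array([p[1] for p in probs])
    return names[rng.choice(len(names), p=w / w.sum())]


def _endogenous_taxa(
    rng: np.random.Generator, params: SampleTypeParams, sample_type: str
) -> tuple[list[dict], dict[str, float]]:
    """Draw the species pool for one sample type: shared core + per-host
    private species, with phylum assignments, genome lengths, extraction
    efficiencies, per-taxon live fractions and freeze-thaw survivals."""
    taxa: list[dict] = []
    freezing_beta = dict(params.freezing_beta)
    survivals: dict[str, float] = {}

    def new_species(name: str, host: str | None) -> dict:
        phylum = _draw_phylum(rng, params.phylum_probs)
        gram = _PHYLUM_GRAM[phylum]
        eff = (
            float(rng.beta(5, 5)) if gram == "positive" else float(rng.beta(8, 2))
        )
        a, b = freezing_beta.get(phylum, (2.0, 8.0))
        survivals[name] = float(rng.beta(a, b))
        return dict(
            name=name, phylum=phylum, gram=gram,
            genome_length=float(rng.uniform(2.0e6, 6.0e6)),
            extraction_efficiency=max(eff, 1e-3),
            weight=float(rng.lognormal(0.0, params.weight_sigma)),
            live_frac_a=params.live_frac_beta[0],
            live_frac_b=params.live_frac_beta[1],
            host=host,  # None = core (present in every host)
        )

    st = sample_type[:3]
    for i in range(params.n_core_species):
        taxa.append(new_species(f"Core{st} species{i + 1:03d}", None))
    return taxa, survivals


def generate_study(
    config: StudyConfig | Mapping | None = None, seed: int = 0
) -> StudyData:
    """Generate a complete synthetic viability study.

    A single root seed derives independent per-sample substreams (via
    ``SeedSequence`` spawn keys), so regenerating with more replicates or
    hosts never perturbs the samples already present. Returns observables in
    the exact dialects the analysis modules read, plus ground truth.
    """
    if config is None:
        config = StudyConfig()
    elif isinstance(config, Mapping):
        config = StudyConfig.from_dict(config)
    root = np.random.SeedSequence(seed)

    meta_rows, qpcr_rows, acct_rows = [], [], []
    truth_load_rows, truth_taxa_rows = [], []
    taxon_tables: dict[str, pd.DataFrame] = {}

    # Noisy standard-curve points (one shared plasmid curve for the study).
    curve_rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(99,)))
    sc_rows = []
    for log10_c in range(2, 9):
        for _ in range(2):
            ct = config.assay.curve.intercept + config.assay.curve.slope * log10_c
            sc_rows.append(
                dict(log10_copies=float(log10_c),
                     ct=float(ct + curve_rng.normal(0, config.assay.ct_noise_sd)))
            )
    standard_curve_points = pd.DataFrame(sc_rows)

    spike_assays = [s["name"] for s in SPIKE_STRAINS]

    for t_idx, sample_type in enumerate(config.sample_types):
        params = config.params_for(sample_type)
        pool_rng = np.random.default_rng(
            np.random.SeedSequence(seed, spawn_key=(t_idx, 1000))
        )
        core, survivals = _endogenous_taxa(pool_rng, params, sample_type)
        profiles: dict[str, pd.Series] = {}

        for h_idx in range(config.n_hosts):
            host_id = f"H{h_idx + 1}"
            host_rng = np.random.default_rng(
                np.random.SeedSequence(seed, spawn_key=(t_idx, h_idx, 2000))
            )
            # Per-host private species extend the shared core.
            private = []
            for i in range(params.n_private_species):
                name = f"Private{sample_type[:3]} {host_id} species{i + 1:02d}"
                phylum = _draw_phylum(host_rng, params.phylum_probs)
                gram = _PHYLUM_GRAM[phylum]
                a, b = dict(params.freezing_beta).get(phylum, (2.0, 8.0))
                survivals[name] = float(host_rng.beta(a, b))
                private.append(
                    dict(
                        name=name, phylum=phylum, gram=gram,
                        genome_length=float(host_rng.uniform(2.0e6, 6.0e6)),
                        extraction_efficiency=max(
                            float(host_rng.beta(5, 5) if gram == "positive"
                                  else host_rng.beta(8, 2)), 1e-3),
                        weight=float(host_rng.lognormal(0.0, params.weight_sigma)),
                        live_frac_a=params.live_frac_beta[0],
                        live_frac_b=params.live_frac_beta[1],
                        host=host_id,
                    )
                )
            species = core + private
            # Host-specific composition: core weights perturbed log-normally.
            weights = np.array(
                [s["weight"] * host_rng.lognormal(0.0, params.host_weight_sigma)
                 for s in species]
            )
            live_fracs = host_rng.beta(
                params.live_frac_beta[0], params.live_frac_beta[1], size=len(species)
            )
            native_load = params.load_mean * host_rng.lognormal(
                0.0, params.load_sigma
            )
            copies = weights / weights.sum() * native_load

            # Spike dose: target fraction of the post-spike total.
            f = config.spike_target_fraction
            spike_total = native_load * f / (1.0 - f)
            share_key = f"{sample_type}_share"
            base_taxa = []
            for s, c, lf in zip(species, copies, live_fracs):
                base_taxa.append(
                    TaxonSpec(
                        name=s["name"], phylum=s["phylum"], gram=s["gram"],
                        live_copies=c * lf, dead_copies=c * (1 - lf),
                        genome_length=s["genome_length"],
                        extraction_efficiency=s["extraction_efficiency"],
                    )
                )
                truth_taxa_rows.append(
                    dict(sample_type=sample_type, host_id=host_id, taxon=s["name"],
                         phylum=s["phylum"], gram=s["gram"], core=s["host"] is None,
                         live_fraction=float(lf),
                         freezing_survival=survivals[s["name"]],
                         extraction_efficiency=s["extraction_efficiency"])
                )
            for s in SPIKE_STRAINS:
                dose = spike_total * s[share_key]
                live = dose if s["status"] == "live" else 0.0
                dead = dose if s["status"] == "dead" else 0.0
                survivals.setdefault(s["name"], 1.0 if s["status"] == "live" else 0.0)
                base_taxa.append(
                    TaxonSpec(
                        name=s["name"], phylum=s["phylum"], gram=s["gram"],
                        live_copies=live, dead_copies=dead,
                        genome_length=s["genome_length"],
                        extraction_efficiency=s["extraction_efficiency"],
                        is_spikein=True,
                    )
                )

            # Host-cell signal calibrated to the target pre-treatment
            # host-read fraction given the microbial DNA mass.
            microbial_mass = sum(
                (t.live_copies + t.dead_copies) * t.genome_length
                * t.extraction_efficiency
                for t in base_taxa
            )
            hf = params.host_read_fraction
            host_weight = 1000.0
            host_cells = hf / (1.0 - hf) * microbial_mass / host_weight

            spec = SyntheticCommunitySpec(
                taxa=tuple(base_taxa),
                host_cell_count=host_cells,
                host_genome_mass_weight=host_weight,
            )
            effect = replace(config.treatment, freezing_survival=dict(survivals))

            for g_idx, group in enumerate(config.groups):
                for rep in range(1, config.n_replicates + 1):
                    sid = f"{host_id}_{sample_type}_{group}_r{rep}"
                    ss = np.random.SeedSequence(
                        seed, spawn_key=(t_idx, h_idx, g_idx, rep)
                    )
                    kid_comm, kid_qpcr, kid_seq = ss.spawn(3)
                    comm = make_community(
                        spec, kid_comm,
                        variation_sigma=config.replicate_jitter_sigma,
                    )
                    if group == "lyPMAxx":
                        comm = apply_treatment(comm, effect, "lyPMAxx")
                    elif group == "frozen_lyPMAxx":
                        comm = apply_treatment(comm, effect, "freezing_then_lyPMAxx")

                    meta_rows.append(
                        dict(sample_id=sid, host_id=host_id,
                             sample_type=sample_type, group=group, replicate=rep)
                    )
                    targets = ["universal_16S", "host_marker", *spike_assays]
                    for m in simulate_qpcr(
                        comm, config.assay, targets, sample_id=sid, seed=kid_qpcr
                    ):
                        qpcr_rows.append(
                            dict(sample_id=m.sample_id, assay=m.assay,
                                 replicate=m.replicate,
                                 ct="" if m.censored else round(m.ct, 4))
                        )
                    profile, acct = simulate_sequencing(
                        comm, config.assay, sample_id=sid, seed=kid_seq
                    )
                    profiles[sid] = profile
                    acct_rows.append(asdict(acct))
                    truth_load_rows.append(
                        dict(sample_id=sid, host_id=host_id,
                             sample_type=sample_type, group=group, replicate=rep,
                             unit=params.unit,
                             true_total_amplifiable=comm.total_amplifiable,
                             true_live=float(comm.live.sum()),
                             true_dead=float(comm.dead.sum()))
                    )

        table = pd.DataFrame(profiles).fillna(0.0) * 100.0  # profiler percent dialect
        table.index.name = "lineage"
        taxon_tables[sample_type] = table

    return StudyData(
        metadata=pd.DataFrame(meta_rows),
        qpcr=pd.DataFrame(qpcr_rows),
        standard_curve_points=standard_curve_points,
        taxon_tables=taxon_tables,
        read_accounting=pd.DataFrame(acct_rows),
        truth_loads=pd.DataFrame(truth_load_rows),
        truth_taxa=pd.DataFrame(truth_taxa_rows),
        config=config,
        seed=seed,
    )


def write_study(study: StudyData, outdir) -> dict[str, str]:
    """Write a generated study to disk in the analysis modules' dialects.

    Emits metadata.csv, qpcr.csv, standard_curve.csv, read_accounting.csv,
    taxon_<type>.tsv, truth_loads.csv, truth_taxa.csv and study.json
    (seed + content hash). Returns the path map.
    """
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    def _w(name, frame, **kw):
        p = out / name
        frame.to_csv(p, index=kw.pop("index", False), **kw)
        paths[name] = str(p)

    _w("metadata.csv", study.metadata)
    _w("qpcr.csv", study.qpcr)
    _w("standard_curve.csv", study.standard_curve_points)
    _w("read_accounting.csv", study.read_accounting)
    _w("truth_loads.csv", study.truth_loads)
    _w("truth_taxa.csv", study.truth_taxa)
    for st, table in study.taxon_tables.items():
        _w(f"taxon_{st}.tsv", table, sep="\t", index=True)
    manifest = dict(seed=study.seed, content_hash=study.content_hash(),
                    n_samples=len(study.metadata))
    (out / "study.json").write_text(json.dumps(manifest, indent=2))
    paths["study.json"] = str(out / "study.json")
    return paths
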