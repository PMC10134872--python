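"""Relative -> absolute abundance, spike-in handling, and fold-change calls.

Relative taxon profiles (MetaPhlAn-style lineage x sample tables) are
compositional: a treatment that kills half the community can leave relative
abundances untouched. Scaling each sample's composition by its qPCR-derived
microbiota load yields *absolute* abundances (copies per mL/g), on which
treatment effects become directly comparable across samples and hosts.

Fold changes between groups are taken on species shared across all hosts,
paired by (host, replicate), tested with an exact Wilcoxon signed-rank, and
classified against fold thresholds into treatment-responsive (large drop),
resilient (small drop) and intermediate species.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedRatioError, UnitMismatchError
from .qpcr import MicrobiotaLoad

__all__ = [
    "SampleRecord",
    "TaxonTable",
    "ReadAccounting",
    "AbsoluteAbundanceTable",
    "FoldChangeResult",
    "WilcoxonResult",
    "read_taxon_table",
    "taxon_table_from_frame",
    "strip_spikeins",
    "host_read_fraction",
    "absolute_abundance",
    "shared_species",
    "species_fold_change",
    "classify_response",
    "wilcoxon_signed_rank",
    "RESPONSE_PRESETS",
    "species_token",
]

#: Fold-change classification presets (responsive_min, resilient_max):
#: a species is *responsive* above the first threshold and *resilient*
#: below the second.
RESPONSE_PRESETS: dict[str, tuple[float, float]] = {
    "lyPMAxx": (4.0, 2.5),
    "freezing_saliva": (10.0, 2.5),
    "freezing_feces": (25.0, 2.5),
}

GROUPS = ("control", "lyPMAxx", "frozen_lyPMAxx")
SAMPLE_TYPES = ("saliva", "feces")

_RANK_PREFIXES = ("k__", "p__", "c__", "o__", "f__", "g__", "s__")


@dataclass(frozen=True)
class SampleRecord:
    """Study metadata for one sequenced/assayed sample."""

    sample_id: str
    host_id: str
    sample_type: str
    group: str
    replicate: int

    def __post_init__(self):
        if self.sample_type not in SAMPLE_TYPES:
            raise InvalidInputError(f"unknown sample_type {self.sample_type!r}")
        if self.group not in GROUPS:
            raise InvalidInputError(f"unknown group {self.group!r}")
        if self.replicate < 1:
            raise InvalidInputError("replicate must be a positive integer")


@dataclass(frozen=True)
class ReadAccounting:
    """Read-count bookkeeping for one sample.

    ``microbial_reads`` includes any spike-in reads; ``spikein_reads`` counts
    them separately so they can be excluded from the host-fraction rule.
    """

    sample_id: str
    host_reads: int
    microbial_reads: int
    spikein_reads: int = 0

    def __post_init__(self):
        if min(self.host_reads, self.microbial_reads, self.spikein_reads) < 0:
            raise InvalidInputError("read counts must be nonnegative")
        if self.spikein_reads > self.microbial_reads:
            raise InvalidInputError("spikein_reads cannot exceed microbial_reads")


def species_token(name: str) -> str:
    """Normalise a species name for exact matching: underscores -> spaces,
    collapsed whitespace. The species token of a full lineage is the part
    after ``s__``."""
    if "s__" in name:
        name = name.rsplit("s__", 1)[1]
    return re.sub(r"[\s_]+", " ", name).strip()


def _lineage_rank(lineage: str) -> str:
    """Deepest rank prefix present in a pipe-delimited lineage string."""
    last = lineage.split("|")[-1]
    for p in _RANK_PREFIXES:
        if last.startswith(p):
            return p
    return ""


class TaxonTable:
    """Lineage x sample table of relative abundances (per-sample sum = 1).

    ``data`` is a DataFrame indexed by full lineage strings
    (``k__...|p__...|...|s__...``) with one column per sample, values in
    [0, 1] summing to 1 per column.
    """

    def __init__(self, data: pd.DataFrame, *, renormalize: bool = True):
        if data.index.duplicated().any():
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise InvalidInputError(f"duplicate lineages: {dups}")
        if (data.values < 0).any():
            raise InvalidInputError("relative abundances must be nonnegative")
        data = data.astype(float)
        sums = data.sum(axis=0)
        empty = sums[sums == 0].index.tolist()
        if empty:
            warnings.warn(f"samples with zero total abundance: {empty}", stacklevel=2)
        if renormalize:
            nonzero = sums[sums > 0].index
            data = data.copy()
            data[nonzero] = data[nonzero] / sums[nonzero]
        self.data = data

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def lineages(self) -> list[str]:
        return list(self.data.index)

    def at_rank(self, rank: Literal["k", "p", "c", "o", "f", "g", "s"]) -> "TaxonTable":
        """Rows whose deepest rank matches, renormalised per sample."""
        prefix = f"{rank}__"
        mask = [_lineage_rank(l) == prefix for l in self.data.index]
        if not any(mask):
            raise InvalidInputError(f"no rows at rank {rank!r}")
        return TaxonTable(self.data.loc[mask])

    def species_level(self) -> "TaxonTable":
        return self.at_rank("s")

    def species_names(self) -> list[str]:
        return [species_token(l) for l in self.data.index]

    def __repr__(self):
        return f"TaxonTable({self.data.shape[0]} taxa x {self.data.shape[1]} samples)"


class AbsoluteAbundanceTable:
    """Taxon table scaled to absolute copies per unit; per-sample column sums
    equal the sample's microbiota load."""

    def __init__(self, data: pd.DataFrame, loads: Mapping[str, MicrobiotaLoad]):
        self.data = data.astype(float)
        self.loads = dict(loads)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def __repr__(self):
        return (
            f"AbsoluteAbundanceTable({self.data.shape[0]} taxa x "
            f"{self.data.shape[1]} samples)"
        )


class WilcoxonResult(NamedTuple):
    statistic: float  # sum of positive ranks (W+)
    p_value: float
    n_nonzero: int
    degenerate: bool = False


@dataclass(frozen=True)
class FoldChangeResult:
    """Control-vs-treated contrast for one species (fold > 1 = depletion)."""

    species: str
    mean_abs_control: float
    mean_abs_treated: float
    fold_change: float
    p_value: float
    response_class: str = "not_evaluated"
    pseudocount_used: bool = False
    n_pairs: int = 0


# ---------------------------------------------------------------------------
# Table I/O and transforms
# ---------------------------------------------------------------------------


def taxon_table_from_frame(df: pd.DataFrame) -> TaxonTable:
    """Build a TaxonTable from a lineage-indexed DataFrame, auto-detecting
    whether values are percentages (column sums near 100) or fractions."""
    sums = df.sum(axis=0)
    positive = sums[sums > 0]
    if len(positive) and (positive > 50).all():
        df = df / 100.0
    return TaxonTable(df)


def read_taxon_table(path) -> TaxonTable:
    """Read a MetaPhlAn-style merged TSV: a lineage column (``clade_name`` or
    first column) and one column per sample; values may be percentages or
    fractions (auto-detected by column sums)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    lineage_col = df.columns[0]
    df = df.set_index(lineage_col)
    df.index.name = "lineage"
    non_numeric = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if non_numeric:
        df = df.drop(columns=non_numeric)
    return taxon_table_from_frame(df)


def strip_spikeins(
    table: TaxonTable, spike_taxa: Sequence[str]
) -> tuple[TaxonTable, pd.Series]:
    """Remove spike-in species rows and renormalise the endogenous community.

    Matching is exact on the species token (after underscore/space
    normalisation). A spike taxon absent everywhere triggers a warning, not an
    error: low-extraction strains can legitimately be undetectable. Returns
    the stripped table and the removed relative mass per sample.
    """
    targets = {species_token(t) for t in spike_taxa}
    tokens = pd.Index([species_token(l) for l in table.data.index])
    is_spike = tokens.isin(targets)
    found = set(tokens[is_spike])
    missing = targets - found
    if missing:
        warnings.warn(
            f"spike taxa not detected in the table: {sorted(missing)}", stacklevel=2
        )
    removed_mass = table.data.loc[list(is_spike)].sum(axis=0)
    kept = table.data.loc[[not s for s in is_spike]]
    dead_cols = kept.columns[kept.sum(axis=0) == 0]
    nonempty_before = table.data.sum(axis=0) > 0
    fully_spike = [c for c in dead_cols if nonempty_before[c]]
    if fully_spike:
        raise InvalidInputError(
            f"samples consist entirely of spike-in taxa: {fully_spike}"
        )
    return TaxonTable(kept), removed_mass.rename("removed_mass")


def host_read_fraction(acct: ReadAccounting) -> float:
    """Host-read proportion with spike-in reads excluded from the microbial
    denominator: ``host / (host + (microbial - spikein))``."""
    microbial = acct.microbial_reads - acct.spikein_reads
    denom = acct.host_reads + microbial
    if denom <= 0:
        raise UndefinedRatioError(
            f"sample {acct.sample_id}: zero reads after spike-in removal"
        )
    return acct.host_reads / denom


def absolute_abundance(
    table: TaxonTable, loads: Mapping[str, MicrobiotaLoad]
) -> AbsoluteAbundanceTable:
    """Scale each sample's relative abundances by its microbiota load."""
    missing = [s for s in table.sample_ids if s not in loads]
    if missing:
        raise InvalidInputError(f"no microbiota load for samples: {missing}")
    units = {loads[s].unit for s in table.sample_ids}
    if len(units) > 1:
        raise UnitMismatchError(f"mixed load units across samples: {units}")
    scaled = table.data.mul(
        pd.Series({s: loads[s].copies_per_unit for s in table.sample_ids}), axis=1
    )
    return AbsoluteAbundanceTable(scaled, loads)


def shared_species(
    table: TaxonTable,
    records: Sequence[SampleRecord],
    sample_type: str,
    *,
    groups: Sequence[str] = ("control",),
) -> list[str]:
    """Species detected in every host for a sample type.

    A species counts as present in a host if its relative abundance is
    positive in at least one replicate of the reference group(s) (default:
    control only). Returns species tokens in deterministic alphabetical order.
    """
    recs = [r for r in records if r.sample_type == sample_type and r.group in groups]
    hosts = sorted({r.host_id for r in recs})
    if len(hosts) < 2:
        raise InvalidInputError("shared_species needs >= 2 hosts")
    sp_table = table.species_level()
    tokens = np.array(sp_table.species_names())
    shared: set[str] | None = None
    for host in hosts:
        cols = [r.sample_id for r in recs if r.host_id == host]
        cols = [c for c in cols if c in sp_table.data.columns]
        if not cols:
            raise InvalidInputError(f"host {host}: no samples present in the table")
        present = set(tokens[(sp_table.data[cols] > 0).any(axis=1).values])
        shared = present if shared is None else shared & present
    return sorted(shared or ())


# ---------------------------------------------------------------------------
# Paired statistics
# ---------------------------------------------------------------------------


def wilcoxon_signed_rank(
    pairs: Sequence[tuple[float, float]] | np.ndarray,
    *,
    exact_limit: int = 12,
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired observations.

    Zero differences are dropped (Wilcoxon convention) and tied absolute
    differences receive average ranks. For up to ``exact_limit`` nonzero
    differences the null distribution of W+ (sum of positive ranks) is built
    by full enumeration of the 2^n sign assignments, so the p-value is exact
    even under ties; larger n uses the normal approximation with tie and
    continuity corrections. All-zero differences give the degenerate result
    p = 1.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] == 0:
        raise InvalidInputError("pairs must be a nonempty sequence of (a, b)")
    d = arr[:, 0] - arr[:, 1]
    d = d[d != 0]
    n = d.size
    if n == 0:
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_nonzero=0, degenerate=True)
    ranks = stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= exact_limit:
        # Null distribution of W+ over all sign vectors; exact under ties.
        totals = np.zeros(1)
        for r in ranks:
            totals = np.concatenate([totals, totals + r])
        p_le = np.mean(totals <= w_plus + 1e-12)
        p_ge = np.mean(totals >= w_plus - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - ((tie_counts**3 - tie_counts).sum()) / 48.0
        if var == 0:
            return WilcoxonResult(w_plus, 1.0, n, degenerate=True)
        z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / math.sqrt(var)
        p = float(min(1.0, 2.0 * stats.norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_plus, p_value=float(p), n_nonzero=n)


def _bh_adjust(pvals: list[float | None]) -> list[float | None]:
    """Benjamini-Hochberg over the evaluated entries, preserving Nones."""
    from statsmodels.stats.multitest import multipletests

    idx = [i for i, p in enumerate(pvals) if p is not None]
    if not idx:
        return pvals
    adj = multipletests([pvals[i] for i in idx], method="fdr_bh")[1]
    out = list(pvals)
    for i, a in zip(idx, adj):
        out[i] = float(a)
    return out


def species_fold_change(
    abs_table: AbsoluteAbundanceTable,
    records: Sequence[SampleRecord],
    group_a: str = "control",
    group_b: str = "lyPMAxx",
    *,
    species: Sequence[str] | None = None,
    pseudocount_policy: Literal["half_min_positive", "none"] = "half_min_positive",
    pairing: Literal["replicate", "host_mean"] = "replicate",
    adjust: Literal["none", "bh"] = "none",
) -> list[FoldChangeResult]:
    """Per-species fold change (group_a / group_b) with a paired Wilcoxon p.

    Pairing is by (host, replicate index) pooled across hosts (``replicate``,
    n = hosts x replicates pairs) or by per-host means (``host_mean``,
    n = hosts pairs). Folds are ratios of group means; a zero group mean is
    replaced by the pseudocount (half the smallest positive abundance in the
    table) under the default policy, and flagged. Species all-zero in both
    groups, or with no complete pairs, come back ``not_evaluated``.
    """
    sp = abs_table.data
    tokens = [species_token(l) for l in sp.index]
    sp = sp.set_axis(tokens, axis=0)
    recs_a = [r for r in records if r.group == group_a and r.sample_id in sp.columns]
    recs_b = [r for r in records if r.group == group_b and r.sample_id in sp.columns]
    if not recs_a or not recs_b:
        raise InvalidInputError(f"groups {group_a!r}/{group_b!r} not both present")

    by_key_a = {(r.host_id, r.replicate): r.sample_id for r in recs_a}
    by_key_b = {(r.host_id, r.replicate): r.sample_id for r in recs_b}
    if pairing == "replicate":
        keys = sorted(set(by_key_a) & set(by_key_b))
        cols_a = [by_key_a[k] for k in keys]
        cols_b = [by_key_b[k] for k in keys]
    else:  # host-mean pairing: one pair per host
        hosts = sorted({h for h, _ in by_key_a} & {h for h, _ in by_key_b})
        cols_a, cols_b = [], []
        for h in hosts:
            cols_a.append([s for (hh, _), s in sorted(by_key_a.items()) if hh == h])
            cols_b.append([s for (hh, _), s in sorted(by_key_b.items()) if hh == h])

    positive = sp.values[sp.values > 0]
    pseudocount = positive.min() / 2.0 if positive.size else np.nan

    wanted = list(species) if species is not None else sorted(set(tokens))
    results: list[FoldChangeResult] = []
    for name in wanted:
        if name not in sp.index:
            results.append(
                FoldChangeResult(name, math.nan, math.nan, math.nan, math.nan)
            )
            continue
        row = sp.loc[name]
        if isinstance(row, pd.DataFrame):  # duplicated token across lineages
            row = row.sum(axis=0)
        if pairing == "replicate":
            a_vals = row[cols_a].to_numpy(dtype=float)
            b_vals = row[cols_b].to_numpy(dtype=float)
        else:
            a_vals = np.array([row[c].mean() for c in cols_a], dtype=float)
            b_vals = np.array([row[c].mean() for c in cols_b], dtype=float)
        n_pairs = a_vals.size
        if n_pairs == 0 or (not a_vals.any() and not b_vals.any()):
            results.append(
                FoldChangeResult(name, float(a_vals.mean()) if n_pairs else math.nan,
                                 float(b_vals.mean()) if n_pairs else math.nan,
                                 math.nan, math.nan, "not_evaluated", False, n_pairs)
            )
            continue
        mean_a, mean_b = float(a_vals.mean()), float(b_vals.mean())
        used_pc = False
        num, den = mean_a, mean_b
        if pseudocount_policy == "half_min_positive":
            if num == 0:
                num, used_pc = pseudocount, True
            if den == 0:
                den, used_pc = pseudocount, True
        if den == 0:
            raise UndefinedRatioError(
                f"species {name}: zero denominator and pseudocounts disabled"
            )
        wres = wilcoxon_signed_rank(np.column_stack([a_vals, b_vals]))
        results.append(
            FoldChangeResult(
                species=name,
                mean_abs_control=mean_a,
                mean_abs_treated=mean_b,
                fold_change=num / den,
                p_value=wres.p_value,
                response_class="unclassified",
                pseudocount_used=used_pc,
                n_pairs=n_pairs,
            )
        )
    if adjust == "bh":
        pvals = [None if math.isnan(r.p_value) else r.p_value for r in results]
        for i, p in enumerate(_bh_adjust(pvals)):
            if p is not None:
                results[i] = replace(results[i], p_value=p)
    return results


def classify_response(
    results: Iterable[FoldChangeResult],
    thresholds: tuple[float, float] | str = "lyPMAxx",
) -> list[FoldChangeResult]:
    """Label fold changes: responsive above ``responsive_min``, resilient
    below ``resilient_max``, intermediate between. ``thresholds`` may be a
    preset name (lyPMAxx 4/2.5, freezing_saliva 10/2.5, freezing_feces
    25/2.5) or an explicit (responsive_min, resilient_max) pair."""
    if isinstance(thresholds, str):
        try:
            responsive_min, resilient_max = RESPONSE_PRESETS[thresholds]
        except KeyError:
            raise InvalidInputError(
                f"unknown preset {thresholds!r}; choices: {sorted(RESPONSE_PRESETS)}"
            ) from None
    else:
        responsive_min, resilient_max = thresholds
    if not responsive_min > resilient_max > 0:
        raise InvalidInputError(
            f"need responsive_min > resilient_max > 0, got "
            f"({responsive_min}, {resilient_max})"
        )
    out = []
    for r in results:
        if math.isnan(r.fold_change) or r.response_class == "not_evaluated":
            out.append(replace(r, response_class="not_evaluated"))
        elif r.fold_change > responsive_min:
            out.append(replace(r, response_class="responsive"))
        elif r.fold_change < resilient_max:
            out.append(replace(r, response_class="resilient"))
        else:
            out.append(replace(r, response_class="intermediate"))
    return out
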