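"""Core data containers and text-format I/O for the AD signature pipeline.

Everything the pipeline touches on disk is plain tab-separated UTF-8 text:
expression matrices (genes x samples), per-sample annotation tables, GMT
gene-set files (Broad dialect), two-column ortholog maps and two-column
signed gene signatures.  Lines starting with ``#`` are comments.

Writers are byte-stable: rows are sorted by gene symbol, columns by sample
id, and floats are rendered with 6 significant digits, so identical inputs
always produce identical files.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger("adsigkit")

VALUE_KINDS = ("counts", "log_intensity", "tpm")
LESIONAL_LEVELS = ("control", "lesional", "nonlesional")
TIMEPOINT_LEVELS = ("baseline", "week2", "week12")
ANNOTATION_FIELDS = ("group", "lesional", "scorad", "subject", "timepoint")

FLOAT_FMT = "%.6g"


class ValidationError(ValueError):
    """Raised when an on-disk file or in-memory object violates a contract."""


# ---------------------------------------------------------------------------
# run report
# ---------------------------------------------------------------------------


@dataclass
class RunReport:
    """Accumulates per-stage counts and warnings for reproducibility audits."""

    counts: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    seeds: dict = field(default_factory=dict)

    def count(self, key: str, value: int) -> None:
        self.counts[key] = int(value)

    def warn(self, message: str) -> None:
        self.warnings.append(str(message))
        logger.warning(message)

    def as_dict(self) -> dict:
        return {"counts": dict(self.counts), "warnings": list(self.warnings),
                "seeds": dict(self.seeds)}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


def _check_unique(labels: Iterable[str], what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = sorted(set(idx[idx.duplicated()]))
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values plus per-sample annotations.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns.  ``value_kind`` is one of ``counts`` (non-negative integers,
    RNA-seq), ``log_intensity`` (real, log2-scale microarray) or ``tpm``.
    ``samples`` is a DataFrame indexed by sample id carrying the clinical
    annotations used downstream (group, lesional status, SCORAD, subject,
    timepoint); missing annotations are NA.
    """

    values: pd.DataFrame
    value_kind: str
    samples: pd.DataFrame = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.value_kind not in VALUE_KINDS:
            raise ValidationError(
                f"value_kind must be one of {VALUE_KINDS}, got {self.value_kind!r}")
        _check_unique(self.values.index, "gene ids")
        _check_unique(self.values.columns, "sample ids")
        vals = self.values.to_numpy()
        if self.value_kind == "counts":
            if np.any(vals < 0) or np.any(vals != np.floor(vals)):
                bad = np.argwhere((vals < 0) | (vals != np.floor(vals)))[0]
                raise ValidationError(
                    "counts must be non-negative integers; offending cell "
                    f"gene={self.values.index[bad[0]]!r} "
                    f"sample={self.values.columns[bad[1]]!r} "
                    f"value={vals[bad[0], bad[1]]}")
        elif self.value_kind == "tpm":
            if np.any(vals < 0):
                raise ValidationError("tpm values must be non-negative")
        if self.samples is None:
            self.samples = _empty_annotations(self.values.columns)
        else:
            self.samples = _conform_annotations(self.samples, self.values.columns)

    # convenience -----------------------------------------------------------

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        return ExpressionMatrix(self.values.loc[genes], self.value_kind,
                                self.samples.copy())

    def subset_samples(self, sample_ids: Iterable[str]) -> "ExpressionMatrix":
        ids = list(sample_ids)
        return ExpressionMatrix(self.values[ids], self.value_kind,
                                self.samples.loc[ids])

    def samples_in_group(self, group: str) -> list:
        mask = self.samples["group"] == group
        return list(self.samples.index[mask])


def _empty_annotations(sample_ids: pd.Index) -> pd.DataFrame:
    ann = pd.DataFrame(index=pd.Index(sample_ids, name="sample"),
                       columns=list(ANNOTATION_FIELDS), dtype=object)
    ann["scorad"] = np.nan
    return ann


def _conform_annotations(ann: pd.DataFrame, sample_ids: pd.Index) -> pd.DataFrame:
    _check_unique(ann.index, "annotation sample ids")
    out = _empty_annotations(sample_ids)
    shared = [s for s in sample_ids if s in ann.index]
    for col in ANNOTATION_FIELDS:
        if col in ann.columns:
            out.loc[shared, col] = ann.loc[shared, col].to_numpy()
    out["scorad"] = pd.to_numeric(out["scorad"], errors="coerce")
    if np.any(out["scorad"].dropna() < 0):
        raise ValidationError("scorad must be non-negative")
    for col, levels in (("lesional", LESIONAL_LEVELS), ("timepoint", TIMEPOINT_LEVELS)):
        bad = out[col].dropna()
        bad = bad[~bad.isin(levels)]
        if len(bad):
            raise ValidationError(f"invalid {col} labels: {sorted(set(bad))}")
    return out


@dataclass
class ProbeMap:
    """Many-to-one mapping from array probe id to gene symbol."""

    mapping: pd.Series  # index: probe id, value: gene symbol

    def __post_init__(self) -> None:
        _check_unique(self.mapping.index, "probe ids")
        self.mapping = self.mapping.astype(str)

    def genes_for(self, probes: Iterable[str]) -> pd.Series:
        return self.mapping.reindex(list(probes))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. KEGG pathways) with free-text descriptions."""

    sets: dict  # name -> (description, tuple of member symbols)

    def __post_init__(self) -> None:
        for name, (_desc, members) in self.sets.items():
            if len(members) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            _check_unique(members, f"members of gene set {name!r}")
            self.sets[name] = (_desc, tuple(members))

    def __len__(self) -> int:
        return len(self.sets)

    def members(self, name: str) -> tuple:
        return self.sets[name][1]

    def names(self) -> list:
        return list(self.sets)

    def map_symbols(self, symbol_map: Mapping[str, str]) -> "GeneSetCollection":
        """Translate members through a symbol map, dropping unmapped genes."""
        out = {}
        for name, (desc, members) in self.sets.items():
            mapped = []
            for g in members:
                if g in symbol_map and symbol_map[g] not in mapped:
                    mapped.append(symbol_map[g])
            if mapped:
                out[name] = (desc, tuple(mapped))
        return GeneSetCollection(out)


@dataclass
class OrthologMap:
    """Mouse -> human gene symbol pairs.

    The raw pair list may contain one-to-many or many-to-one relations; the
    ``working`` map used for cross-species intersection keeps only the
    strictly one-to-one pairs, and the discarded ambiguous pairs are exposed
    for reporting.
    """

    pairs: pd.DataFrame  # columns: mouse, human

    def __post_init__(self) -> None:
        pairs = self.pairs[["mouse", "human"]].astype(str).drop_duplicates()
        mouse_multi = pairs["mouse"].duplicated(keep=False)
        human_multi = pairs["human"].duplicated(keep=False)
        self._ambiguous = pairs[mouse_multi | human_multi].reset_index(drop=True)
        self._working = pairs[~(mouse_multi | human_multi)].reset_index(drop=True)
        self.pairs = pairs.reset_index(drop=True)

    @property
    def working(self) -> pd.Series:
        """One-to-one mouse -> human map after ambiguity filtering."""
        return pd.Series(self._working["human"].to_numpy(),
                         index=self._working["mouse"].to_numpy())

    @property
    def ambiguous_pairs(self) -> pd.DataFrame:
        return self._ambiguous.copy()

    def to_human(self, mouse_genes: Iterable[str],
                 report: RunReport | None = None) -> pd.Series:
        """Map mouse symbols to human symbols, dropping unmapped genes."""
        genes = list(mouse_genes)
        mapped = self.working.reindex(genes).dropna()
        if report is not None:
            report.count("ortholog_unmapped_dropped", len(genes) - len(mapped))
        return mapped


@dataclass
class SignatureTable:
    """Signed gene signature: symbol -> weight in {+1, -1}."""

    weights: pd.Series  # index: gene symbol, values: +1/-1

    def __post_init__(self) -> None:
        _check_unique(self.weights.index, "signature genes")
        w = pd.to_numeric(self.weights, errors="coerce")
        if w.isna().any() or not set(np.unique(w)) <= {-1, 1}:
            bad = self.weights[~w.isin([-1, 1])]
            raise ValidationError(
                f"signature weights must be +1 or -1; offending entries: "
                f"{dict(bad)}")
        self.weights = w.astype(int)

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def genes(self) -> pd.Index:
        return self.weights.index


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", index_col=0)


def read_expression_matrix(path, value_kind: str,
                           sample_annotation_path=None) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column gene id, header sample ids).

    Sample annotations, if given, come from a separate TSV keyed by sample
    id; samples present in the matrix but absent there get NA annotations.
    """
    raw = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    raw.index = raw.index.astype(str)
    raw.columns = raw.columns.astype(str)
    _check_unique(raw.index, f"gene ids in {path}")
    _check_unique(raw.columns, f"sample ids in {path}")
    ann = None
    if sample_annotation_path is not None:
        ann = pd.read_csv(sample_annotation_path, sep="\t", comment="#",
                          index_col=0)
        ann.index = ann.index.astype(str)
    return ExpressionMatrix(raw, value_kind, ann)


def write_expression_matrix(m: ExpressionMatrix, path,
                            annotation_path=None) -> None:
    out = m.values.sort_index(axis=0).sort_index(axis=1)
    out.to_csv(path, sep="\t", float_format=FLOAT_FMT, index_label="gene")
    if annotation_path is not None:
        ann = m.samples.sort_index()
        ann.to_csv(annotation_path, sep="\t", float_format=FLOAT_FMT,
                   index_label="sample")


def read_probe_map(path) -> ProbeMap:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["probe", "gene"], dtype=str)
    return ProbeMap(pd.Series(df["gene"].to_numpy(), index=df["probe"].to_numpy()))


def write_probe_map(pm: ProbeMap, path) -> None:
    pm.mapping.sort_index().to_csv(path, sep="\t", header=False)


def read_gene_sets(path) -> GeneSetCollection:
    """Read a Broad-dialect GMT file: name <tab> description <tab> members..."""
    sets = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValidationError(
                    f"GMT line with fewer than 3 fields: {line[:60]!r}")
            name, desc, members = parts[0], parts[1], [p for p in parts[2:] if p]
            if name in sets:
                raise ValidationError(f"duplicate gene set name {name!r}")
            sets[name] = (desc, tuple(dict.fromkeys(members)))
    return GeneSetCollection(sets)


def write_gene_sets(gs: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name in sorted(gs.sets):
            desc, members = gs.sets[name]
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_ortholog_map(path) -> OrthologMap:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["mouse", "human"], dtype=str)
    return OrthologMap(df)


def write_ortholog_map(om: OrthologMap, path) -> None:
    om.pairs.sort_values(["mouse", "human"]).to_csv(
        path, sep="\t", header=False, index=False)


def read_signature(path) -> SignatureTable:
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["gene", "weight"], dtype={"gene": str})
    return SignatureTable(pd.Series(df["weight"].to_numpy(),
                                    index=df["gene"].to_numpy()))


def write_signature(sig: SignatureTable, path) -> None:
    sig.weights.sort_index().to_csv(path, sep="\t", header=False)


def load_ad36_signature() -> SignatureTable:
    """The packaged 36-gene AD signature (27 up-, 9 down-weighted genes)."""
    ref = importlib.resources.files("adsigkit") / "data" / "ad36_signature.tsv"
    with importlib.resources.as_file(ref) as path:
        return read_signature(path)


# ---------------------------------------------------------------------------
# probe collapsing
# ---------------------------------------------------------------------------


def collapse_probes(m: ExpressionMatrix, pm: ProbeMap,
                    report: RunReport | None = None) -> ExpressionMatrix:
    """Collapse a probe-level matrix to one row per gene by geometric mean.

    For log2-intensity input the geometric mean of the natural-scale values
    equals the arithmetic mean of the log2 values, which is the path taken;
    natural-scale input must be strictly positive for the geometric mean to
    be defined.  Probes absent from the map are dropped (and counted in the
    report).
    """
    genes = pm.genes_for(m.values.index)
    keep = genes.notna().to_numpy()
    n_dropped = int((~keep).sum())
    if report is not None:
        report.count("probes_without_gene_dropped", n_dropped)
    if n_dropped:
        logger.info("collapse_probes: dropped %d unmapped probes", n_dropped)
    vals = m.values.loc[keep]
    gene_of = genes[keep].to_numpy()
    if m.value_kind == "log_intensity":
        logvals = vals
    else:
        arr = vals.to_numpy(dtype=float)
        if np.any(arr <= 0):
            bad = np.argwhere(arr <= 0)[0]
            raise ValidationError(
                "geometric mean undefined for non-positive value at probe "
                f"{vals.index[bad[0]]!r}, sample {vals.columns[bad[1]]!r}")
        logvals = pd.DataFrame(np.log2(arr), index=vals.index,
                               columns=vals.columns)
    collapsed_log = logvals.groupby(gene_of).mean()
    if m.value_kind == "log_intensity":
        collapsed = collapsed_log
    else:
        collapsed = pd.DataFrame(np.exp2(collapsed_log.to_numpy()),
                                 index=collapsed_log.index,
                                 columns=collapsed_log.columns)
    collapsed.index.name = m.values.index.name
    return ExpressionMatrix(collapsed, m.value_kind, m.samples.copy())


# ---------------------------------------------------------------------------
# fixture helpers
# ---------------------------------------------------------------------------


def naive_mouse_to_human_symbols(mouse_genes: Iterable[str]) -> dict:
    """Upper-case capitalization map (Cxcl1 -> CXCL1).

    A convenience for building synthetic fixtures only; real ortholog
    relations are not a capitalization rule, so this is never applied
    implicitly anywhere in the pipeline.
    """
    return {g: g.upper() for g in mouse_genes}
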