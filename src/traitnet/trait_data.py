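"""Data model and I/O for trait tables and community samples.

Two tabular inputs drive everything downstream:

* a **trait table**: taxa in rows, trait modalities in columns, with each
  modality labelled by the category it belongs to — ecosystem-regulating
  (``REG``), recovery-enhancing/-inhibiting (``REC_e``/``REC_i``) or
  resistance-enhancing/-inhibiting (``RES_e``/``RES_i``);
* **community data**: long-form records of (site, treatment, plot, taxon,
  count), optionally with per-site environmental covariates.

The module also provides binarization of fuzzy-coded trait scores and the
pooling of replicate plots into one species list per site-treatment, which
is the community unit the co-occurrence model operates on.

File dialects
-------------
Trait table CSV: first column ``taxon``; one header row naming modalities;
two metadata rows prefixed ``#category`` (required) and ``#trait``
(optional parent-trait names, defaults to the modality id). Community CSV:
long form with columns ``site,treatment,plot,taxon,count``; treatments are
exactly ``control``, ``medium``, ``high``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: The five admissible modality categories.
CATEGORIES = ("REG", "REC_e", "REC_i", "RES_e", "RES_i")

#: The three admissible treatments, in experimental order.
TREATMENTS = ("control", "medium", "high")

CATEGORY_ROW = "#category"
TRAIT_ROW = "#trait"
TAXON_COL = "taxon"


class TraitDataError(ValueError):
    """Raised on malformed trait tables or community data."""


@dataclass(frozen=True)
class TraitModality:
    """One discrete level of a biological trait (a node of the trait network).

    Parameters
    ----------
    id : str
        Short unique label, e.g. ``"feed_susp"``.
    trait : str
        Parent trait name, e.g. ``"feeding mode"``.
    category : str
        One of :data:`CATEGORIES`.
    """

    id: str
    trait: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise TraitDataError(
                f"unknown trait category {self.category!r} for modality "
                f"{self.id!r}; expected one of {', '.join(CATEGORIES)}"
            )


@dataclass
class TraitMatrix:
    """Taxa × trait-modality incidence scores.

    Scores may be fuzzy-coded (non-negative reals); the co-occurrence model
    requires presence/absence, obtained via :func:`binarize_traits`.
    """

    taxa: list[str]
    modalities: list[TraitModality]
    scores: np.ndarray
    binary: bool = False

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        n_taxa, n_mod = len(self.taxa), len(self.modalities)
        if self.scores.shape != (n_taxa, n_mod):
            raise TraitDataError(
                f"score matrix shape {self.scores.shape} does not match "
                f"{n_taxa} taxa x {n_mod} modalities"
            )
        if len(set(self.taxa)) != n_taxa:
            dupes = sorted({t for t in self.taxa if self.taxa.count(t) > 1})
            raise TraitDataError(f"duplicate taxa in trait table: {dupes}")
        ids = [m.id for m in self.modalities]
        if len(set(ids)) != n_mod:
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise TraitDataError(f"duplicate modality ids: {dupes}")
        if np.any(self.scores < 0):
            raise TraitDataError("trait scores must be non-negative")
        if self.binary and not np.isin(self.scores, (0.0, 1.0)).all():
            raise TraitDataError("binary trait matrix contains non-0/1 scores")
        if n_taxa and n_mod and np.any(self.scores.sum(axis=1) == 0):
            empty = [t for t, row in zip(self.taxa, self.scores) if row.sum() == 0]
            raise TraitDataError(f"taxa with no nonzero trait score: {empty}")

    @property
    def modality_ids(self) -> list[str]:
        return [m.id for m in self.modalities]

    def modality(self, mod_id: str) -> TraitModality:
        for m in self.modalities:
            if m.id == mod_id:
                return m
        raise KeyError(mod_id)

    def row(self, taxon: str) -> np.ndarray:
        try:
            return self.scores[self.taxa.index(taxon)]
        except ValueError:
            raise KeyError(taxon) from None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.scores, index=self.taxa, columns=self.modality_ids)


@dataclass
class CommunityData:
    """Long-form community records plus optional per-site covariates.

    ``records`` columns: site, treatment, plot, taxon, count.
    ``covariates`` (optional) is indexed by site; conventional columns are
    ``mean_par`` (µmol photons m⁻² s⁻¹) and ``porewater_nh4``.
    """

    records: pd.DataFrame
    covariates: pd.DataFrame | None = None

    REQUIRED = ("site", "treatment", "plot", "taxon", "count")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.records.columns]
        if missing:
            raise TraitDataError(f"community records missing columns: {missing}")
        rec = self.records
        bad_tr = set(rec["treatment"]) - set(TREATMENTS)
        if bad_tr:
            raise TraitDataError(
                f"unknown treatment values {sorted(bad_tr)}; "
                f"expected {', '.join(TREATMENTS)}"
            )
        counts = rec["count"].to_numpy()
        if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
            raise TraitDataError("counts must be non-negative integers")
        keys = rec[["site", "treatment", "plot", "taxon"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0].tolist()
            raise TraitDataError(
                f"duplicate (site, treatment, plot, taxon) record: {dup}"
            )

    @property
    def sites(self) -> list:
        return sorted(self.records["site"].unique())

    @property
    def taxa(self) -> list[str]:
        return sorted(self.records["taxon"].unique())


@dataclass(frozen=True)
class SiteTreatmentCommunity:
    """The pooled species list of one site-treatment (the network's community).

    ``n_species`` is the community species pool size N used by the
    co-occurrence model.
    """

    site: object
    treatment: str
    presence: frozenset[str]

    @property
    def n_species(self) -> int:
        return len(self.presence)


# ---------------------------------------------------------------------------
# I/O


def read_trait_table(path: str | Path) -> TraitMatrix:
    """Read a trait-table CSV into a :class:`TraitMatrix`.

    Row order is preserved. Unknown category labels and duplicate taxa are
    rejected with the offending value named.
    """
    df = pd.read_csv(path, header=0, dtype=str, keep_default_na=False)
    if df.columns[0] != TAXON_COL:
        raise TraitDataError(
            f"first column of {path} must be {TAXON_COL!r}, got {df.columns[0]!r}"
        )
    mod_ids = [str(c) for c in df.columns[1:]]

    meta_mask = df[TAXON_COL].str.startswith("#")
    meta = df[meta_mask].set_index(TAXON_COL)
    body = df[~meta_mask]

    if CATEGORY_ROW not in meta.index:
        raise TraitDataError(f"trait table {path} lacks a {CATEGORY_ROW!r} row")
    categories = meta.loc[CATEGORY_ROW]
    traits = meta.loc[TRAIT_ROW] if TRAIT_ROW in meta.index else None

    modalities = [
        TraitModality(
            id=mid,
            trait=str(traits[mid]) if traits is not None and traits[mid] else mid,
            category=str(categories[mid]),
        )
        for mid in mod_ids
    ]
    taxa = body[TAXON_COL].tolist()
    scores = body[mod_ids].astype(float).to_numpy()
    binary = bool(np.isin(scores, (0.0, 1.0)).all())
    return TraitMatrix(taxa=taxa, modalities=modalities, scores=scores, binary=binary)


def write_trait_table(matrix: TraitMatrix, path: str | Path) -> None:
    """Write a :class:`TraitMatrix` in the dialect :func:`read_trait_table` reads."""
    header = [TAXON_COL, *matrix.modality_ids]
    rows = [
        [CATEGORY_ROW, *[m.category for m in matrix.modalities]],
        [TRAIT_ROW, *[m.trait for m in matrix.modalities]],
    ]
    for taxon, row in zip(matrix.taxa, matrix.scores):
        fmt = [format(v, "g") for v in row]
        rows.append([taxon, *fmt])
    pd.DataFrame(rows, columns=header).to_csv(path, index=False)


def read_community(
    path: str | Path, covariates_path: str | Path | None = None
) -> CommunityData:
    """Read long-form community CSV (and optional site-covariate CSV)."""
    rec = pd.read_csv(path)
    cov = None
    if covariates_path is not None:
        cov = pd.read_csv(covariates_path).set_index("site")
    return CommunityData(records=rec, covariates=cov)


def write_community(data: CommunityData, path: str | Path,
                    covariates_path: str | Path | None = None) -> None:
    data.records.to_csv(path, index=False)
    if covariates_path is not None and data.covariates is not None:
        data.covariates.to_csv(covariates_path)


# ---------------------------------------------------------------------------
# Transformations


def binarize_traits(matrix: TraitMatrix, threshold: float = 0.0) -> TraitMatrix:
    """Convert fuzzy-coded scores to presence/absence: score > threshold → 1.

    Idempotent at a fixed threshold; the default (0) treats any positive
    affinity as possession of the modality.
    """
    if threshold < 0:
        raise TraitDataError("binarization threshold must be >= 0")
    scores = (matrix.scores > threshold).astype(float)
    return TraitMatrix(
        taxa=list(matrix.taxa),
        modalities=list(matrix.modalities),
        scores=scores,
        binary=True,
    )


def pool_plots(data: CommunityData, site, treatment: str) -> SiteTreatmentCommunity:
    """Union species over a site-treatment's replicate plots.

    A taxon is present if its summed count over the treatment's plots is
    positive. One pooled community is built per site-treatment, matching
    one network per site and enrichment level.
    """
    rec = data.records
    if site not in set(rec["site"]):
        raise TraitDataError(f"unknown site {site!r}")
    if treatment not in TREATMENTS:
        raise TraitDataError(f"unknown treatment {treatment!r}")
    sel = rec[(rec["site"] == site) & (rec["treatment"] == treatment)]
    if sel.empty:
        raise TraitDataError(f"no records for site {site!r}, treatment {treatment!r}")
    totals = sel.groupby("taxon")["count"].sum()
    presence = frozenset(totals[totals > 0].index)
    return SiteTreatmentCommunity(site=site, treatment=treatment, presence=presence)


def pool_all(data: CommunityData) -> list[SiteTreatmentCommunity]:
    """Pooled communities for every (site, treatment) present in the records."""
    pairs = (
        data.records[["site", "treatment"]]
        .drop_duplicates()
        .sort_values(["site", "treatment"])
        .itertuples(index=False)
    )
    return [pool_plots(data, p.site, p.treatment) for p in pairs]
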