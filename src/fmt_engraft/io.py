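"""Input tables, triad assembly, and tree I/O.

Three tab-delimited tables drive an analysis: an ASV count matrix
(samples x ASVs), a seven-rank taxonomy table, and per-sample metadata
linking each recipient's pre-/post-FMT samples to a stool donor. An
optional Newick phylogeny over ASVs enables UniFrac.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")

_ROLE_ALIASES = {
    "donor": "donor",
    "prefmt": "preFMT",
    "pre-fmt": "preFMT",
    "pre_fmt": "preFMT",
    "pre": "preFMT",
    "postfmt": "postFMT",
    "post-fmt": "postFMT",
    "post_fmt": "postFMT",
    "post": "postFMT",
}


class ValidationError(ValueError):
    """Raised when an input table violates its invariants."""


@dataclass(frozen=True)
class AsvTable:
    """Integer ASV count matrix, oriented samples x ASVs.

    ``data`` is a pandas DataFrame indexed by sample id with ASV ids as
    columns. Construction validates non-negativity, integrality, and
    label uniqueness; instances are treated as immutable.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate ASV ids: {dups}")
        values = df.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            frac, _ = np.modf(values.astype(float))
            if np.any(frac != 0):
                i, j = np.argwhere(frac != 0)[0]
                raise ValidationError(
                    "non-integer count at sample "
                    f"{df.index[i]!r}, ASV {df.columns[j]!r}: {values[i, j]!r}"
                )
            object.__setattr__(self, "data", df.astype(np.int64))
            values = self.data.to_numpy()
        if values.size and values.min() < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValidationError(
                f"negative count at sample {df.index[i]!r}, "
                f"ASV {df.columns[j]!r}: {values[i, j]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def asv_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_asvs(self) -> int:
        return self.data.shape[1]

    def counts(self, sample_id: str) -> np.ndarray:
        """Count vector for one sample, aligned with ``asv_ids``."""
        if sample_id not in self.data.index:
            raise KeyError(f"unknown sample id: {sample_id!r}")
        return self.data.loc[sample_id].to_numpy()

    def subset_samples(self, sample_ids: Sequence[str]) -> "AsvTable":
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        return AsvTable(self.data.loc[list(sample_ids)].copy())

    def write_tsv(self, path: str | Path, header_comment: str | None = None) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.data.to_csv(fh, sep="\t", index_label="sample_id")


@dataclass(frozen=True)
class TaxonomyTable:
    """Seven-rank taxonomic labels per ASV; missing ranks are NA."""

    data: pd.DataFrame  # index: asv_id; columns: RANKS

    def __post_init__(self) -> None:
        missing = [r for r in RANKS if r not in self.data.columns]
        if missing:
            raise ValidationError(f"taxonomy table missing rank columns: {missing}")
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate ASV ids in taxonomy table")

    def lowest_classified_label(self, asv_id: str) -> str:
        """Label at the lowest classified rank.

        When the genus (or below) is unclassified, the deepest classified
        label is prefixed ``unclassified`` so that, e.g., an ASV known only
        to family Ruminococcaceae reports as ``unclassified Ruminococcaceae``.
        """
        if asv_id not in self.data.index:
            return "unclassified"
        row = self.data.loc[asv_id]
        label = None
        rank = None
        for r in RANKS:
            v = row[r]
            if _is_classified(v):
                label, rank = str(v).strip(), r
        if label is None:
            return "unclassified"
        if rank in ("genus", "species"):
            return label
        return f"unclassified {label}"


def _is_classified(value: object) -> bool:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return False
    s = str(value).strip()
    return s != "" and s.lower() not in ("unclassified", "na", "nan", "none")


@dataclass(frozen=True)
class SampleRecord:
    """One metadata row: sample identity, host, role, and covariates."""

    sample_id: str
    dog_id: str
    role: str  # donor | preFMT | postFMT
    donor_id: str | None = None
    clinical_signs: str | None = None
    raw_food: bool | None = None
    kibble: bool | None = None
    prior_antibiotics: bool | None = None
    body_condition_score: int | None = None
    donor_primary: bool = False

    def __post_init__(self) -> None:
        if self.role not in ("donor", "preFMT", "postFMT"):
            raise ValidationError(
                f"sample {self.sample_id!r}: invalid role {self.role!r}"
            )
        if self.role != "donor" and not self.donor_id:
            raise ValidationError(
                f"recipient sample {self.sample_id!r} is missing donor_id"
            )
        bcs = self.body_condition_score
        if bcs is not None and not (1 <= bcs <= 9):
            raise ValidationError(
                f"sample {self.sample_id!r}: body_condition_score {bcs} not in [1, 9]"
            )


@dataclass(frozen=True)
class Triad:
    """One recipient's analysis unit: donor, pre-FMT, and post-FMT samples."""

    recipient_id: str
    donor_sample: str
    pre_sample: str
    post_sample: str

    def __post_init__(self) -> None:
        ids = (self.donor_sample, self.pre_sample, self.post_sample)
        if len(set(ids)) != 3:
            raise ValidationError(
                f"triad {self.recipient_id!r}: sample ids not distinct: {ids}"
            )


def read_asv_table(
    path: str | Path,
    format: str = "tsv",
    sample_ids: Iterable[str] | None = None,
    orientation: str = "auto",
) -> AsvTable:
    """Read an ASV count table from TSV, normalising to samples x ASVs.

    Parameters
    ----------
    format
        ``tsv`` for a plain header-row table, ``biom-tsv`` for the classic
        text BIOM export (leading ``#`` comment lines, ``#OTU ID`` header,
        ASVs as rows).
    sample_ids
        Known sample identifiers (from metadata). With ``orientation='auto'``
        the axis whose labels intersect these ids is taken as the sample
        axis; an ambiguous or empty intersection is an error.
    orientation
        ``auto``, ``samples-as-rows``, or ``samples-as-columns``.
    """
    path = Path(path)
    if format == "biom-tsv":
        df = pd.read_csv(path, sep="\t", comment=None, skiprows=_biom_skip(path), index_col=0)
        # classic BIOM text export puts observations (ASVs) on rows
        if orientation == "auto" and sample_ids is None:
            orientation = "samples-as-columns"
    elif format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    else:
        raise ValueError(f"unsupported format: {format!r}")
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)

    if orientation == "auto":
        if sample_ids is None:
            raise ValueError(
                "orientation='auto' requires sample_ids; "
                "otherwise pass orientation explicitly"
            )
        known = set(sample_ids)
        on_rows = len(known.intersection(df.index))
        on_cols = len(known.intersection(df.columns))
        if on_rows and not on_cols:
            orientation = "samples-as-rows"
        elif on_cols and not on_rows:
            orientation = "samples-as-columns"
        else:
            raise ValidationError(
                "cannot orient count table: sample ids matched "
                f"{on_rows} row labels and {on_cols} column labels"
            )
    if orientation == "samples-as-columns":
        df = df.T
    elif orientation != "samples-as-rows":
        raise ValueError(f"unknown orientation: {orientation!r}")
    return AsvTable(df)


def _biom_skip(path: Path) -> list[int]:
    """Rows to skip: leading comments before the '#OTU ID' header."""
    skip = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            if line.startswith("#") and not line.lower().startswith("#otu id"):
                skip.append(i)
            else:
                break
    return skip


_TRUTHY = {"y", "yes", "true", "1", "t"}
_FALSY = {"n", "no", "false", "0", "f"}


def _parse_flag(value: object) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan"):
        return None
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    raise ValidationError(f"cannot interpret flag value {value!r}")


def read_metadata(path: str | Path) -> list[SampleRecord]:
    """Read sample metadata; one :class:`SampleRecord` per row.

    Required columns: ``sample_id``, ``dog_id``, ``role``. Roles are
    normalised case-insensitively (``Donor`` -> ``donor``, ``pre`` ->
    ``preFMT``...). Recipient rows must carry ``donor_id``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    required = ("sample_id", "dog_id", "role")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"metadata missing required columns: {missing}")
    records = []
    for idx, row in df.iterrows():
        role_raw = str(row["role"]).strip().lower()
        if role_raw not in _ROLE_ALIASES:
            raise ValidationError(
                f"metadata row {idx}: unrecognised role {row['role']!r}"
            )
        role = _ROLE_ALIASES[role_raw]
        donor_id = row.get("donor_id")
        if donor_id is not None and (pd.isna(donor_id) or str(donor_id).strip() == ""):
            donor_id = None
        if role != "donor" and donor_id is None:
            raise ValidationError(
                f"metadata row {idx} (sample {row['sample_id']!r}): "
                "recipient sample without donor_id"
            )
        bcs = row.get("body_condition_score")
        bcs_val = None if bcs is None or pd.isna(bcs) else int(float(bcs))
        signs = row.get("clinical_signs")
        records.append(
            SampleRecord(
                sample_id=str(row["sample_id"]).strip(),
                dog_id=str(row["dog_id"]).strip(),
                role=role,
                donor_id=None if donor_id is None else str(donor_id).strip(),
                clinical_signs=None if signs is None or pd.isna(signs) else str(signs).strip().lower(),
                raw_food=_parse_flag(row.get("raw_food")),
                kibble=_parse_flag(row.get("kibble")),
                prior_antibiotics=_parse_flag(row.get("prior_antibiotics")),
                body_condition_score=bcs_val,
                donor_primary=bool(_parse_flag(row.get("donor_primary")) or False),
            )
        )
    seen: set[str] = set()
    for r in records:
        if r.sample_id in seen:
            raise ValidationError(f"duplicate sample_id in metadata: {r.sample_id!r}")
        seen.add(r.sample_id)
    return records


def assemble_triads(
    table: AsvTable,
    records: Sequence[SampleRecord],
    donor_policy: str = "single",
) -> tuple[list[Triad], AsvTable]:
    """Pair each recipient's pre/post samples with its donor sample.

    ``donor_policy`` governs donors represented by multiple fecal samples:

    - ``single``: use the metadata-flagged sample (``donor_primary``); a
      donor with exactly one sample needs no flag.
    - ``pool``: sum all of the donor's samples into one pseudo-sample
      (id ``<donor_id>__pooled``) appended to the returned table.
    - ``error``: abort on any multi-sample donor.

    Returns the triads and the (possibly augmented) count table.
    """
    if donor_policy not in ("single", "pool", "error"):
        raise ValueError(f"unknown donor_policy: {donor_policy!r}")
    by_sample = {r.sample_id: r for r in records}
    for sid in by_sample:
        if sid not in table.data.index:
            raise ValidationError(f"metadata sample {sid!r} absent from count table")

    donor_samples: dict[str, list[SampleRecord]] = {}
    for r in records:
        if r.role == "donor":
            donor_samples.setdefault(r.dog_id, []).append(r)

    data = table.data
    donor_sample_for: dict[str, str] = {}
    for donor_id, samples in sorted(donor_samples.items()):
        if len(samples) == 1:
            donor_sample_for[donor_id] = samples[0].sample_id
            continue
        if donor_policy == "error":
            raise ValidationError(
                f"donor {donor_id!r} has {len(samples)} samples "
                "(donor_policy='error')"
            )
        if donor_policy == "single":
            flagged = [s for s in samples if s.donor_primary]
            if len(flagged) != 1:
                raise ValidationError(
                    f"donor {donor_id!r} has {len(samples)} samples and "
                    f"{len(flagged)} donor_primary flags; expected exactly 1"
                )
            donor_sample_for[donor_id] = flagged[0].sample_id
        else:  # pool
            pooled_id = f"{donor_id}__pooled"
            sids = sorted(s.sample_id for s in samples)
            pooled = data.loc[sids].sum(axis=0)
            data = pd.concat([data, pooled.to_frame(pooled_id).T])
            donor_sample_for[donor_id] = pooled_id

    recipients: dict[str, dict[str, SampleRecord]] = {}
    for r in records:
        if r.role in ("preFMT", "postFMT"):
            recipients.setdefault(r.dog_id, {})
            if r.role in recipients[r.dog_id]:
                raise ValidationError(
                    f"recipient {r.dog_id!r} has multiple {r.role} samples"
                )
            recipients[r.dog_id][r.role] = r

    triads = []
    for dog_id in sorted(recipients):
        pair = recipients[dog_id]
        if "preFMT" not in pair or "postFMT" not in pair:
            missing = {"preFMT", "postFMT"} - set(pair)
            raise ValidationError(
                f"recipient {dog_id!r} is missing samples: {sorted(missing)}"
            )
        donor_ids = {pair[role].donor_id for role in ("preFMT", "postFMT")}
        if len(donor_ids) != 1:
            raise ValidationError(
                f"recipient {dog_id!r}: pre and post samples name different donors"
            )
        donor_id = donor_ids.pop()
        if donor_id not in donor_sample_for:
            raise ValidationError(
                f"recipient {dog_id!r} names unknown donor {donor_id!r}"
            )
        triads.append(
            Triad(
                recipient_id=dog_id,
                donor_sample=donor_sample_for[donor_id],
                pre_sample=pair["preFMT"].sample_id,
                post_sample=pair["postFMT"].sample_id,
            )
        )
    return triads, AsvTable(data)


def read_newick(path: str | Path) -> TreeNode:
    """Read a rooted Newick tree over ASV leaves.

    Missing branch lengths default to 1.0 (with a warning); the root's
    own length is left at 0. Duplicate leaf labels are an error.
    """
    tree = TreeNode.read(str(path))
    return _normalise_tree(tree)


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string (convenience wrapper over :func:`read_newick`)."""
    return _normalise_tree(TreeNode.read(_io.StringIO(newick)))


def _normalise_tree(tree: TreeNode) -> TreeNode:
    names = [leaf.name for leaf in tree.tips()]
    if len(names) != len(set(names)):
        dup = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate leaf labels in tree: {dup}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 1.0
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(
            f"{n_missing} branches had no length; defaulted to 1.0", stacklevel=3
        )
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path))
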