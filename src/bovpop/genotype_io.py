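"""Genotype container and PLINK 1 binary input/output.

The central data structure is :class:`GenotypeDataset`: a sample table, a
marker map, and a samples x markers matrix of allele-A1 dosage calls coded
0/1/2 with a dedicated missing sentinel (:data:`MISSING` = 3, matching the
spare code of the PLINK 2-bit genotype alphabet).  Genotypes are stored
SNP-major on disk in the PLINK 1 bed/bim/fam triplet; population labels and
birth years, which fam files cannot carry, travel in a sidecar TSV keyed by
``sample_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

#: Missing-genotype sentinel in call matrices (never used in arithmetic).
MISSING = np.uint8(3)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # PLINK 1 bed, SNP-major

#: 2-bit bed code -> A1 dosage. 00=hom A1 (2), 01=missing, 10=het, 11=hom A2.
_BED_TO_CALL = np.array([2, 3, 1, 0], dtype=np.uint8)
_CALL_TO_BED = np.array([3, 2, 0, 1], dtype=np.uint8)  # inverse map

_VALID_ALLELES = frozenset("ACGT0")

# Strand-ambiguous (palindromic) allele pairs: A/T and C/G.
_AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class FormatError(ValueError):
    """A file exists but does not conform to the expected binary layout."""


@dataclass
class GenotypeDataset:
    """Samples, marker map, and 0/1/2/missing allele-A1 dosage calls.

    Parameters
    ----------
    samples : pandas.DataFrame
        Columns ``sample_id`` (unique strings), ``population`` (categorical
        label), ``birth_year`` (nullable integer), optional ``sex``.
    markers : pandas.DataFrame
        Columns ``marker_id`` (unique), ``chromosome`` (string label),
        ``position_bp`` (1-based int), ``allele_a1``, ``allele_a2``.
    calls : numpy.ndarray
        ``uint8`` matrix of shape (n_samples, n_markers) with entries in
        {0, 1, 2, MISSING}; each entry counts copies of ``allele_a1``.
    """

    samples: pd.DataFrame
    markers: pd.DataFrame
    calls: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = self.samples.reset_index(drop=True)
        self.markers = self.markers.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.uint8)
        self.validate()

    # -- structure ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    def validate(self) -> None:
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        sid = self.samples["sample_id"]
        if sid.duplicated().any():
            dups = sid[sid.duplicated()].tolist()
            raise ValueError(f"duplicate sample_id values: {dups[:5]}")
        mid = self.markers["marker_id"]
        if mid.duplicated().any():
            dups = mid[mid.duplicated()].tolist()
            raise ValueError(f"duplicate marker_id values: {dups[:5]}")
        for col in ("allele_a1", "allele_a2"):
            bad = set(self.markers[col].astype(str)) - _VALID_ALLELES
            if bad:
                raise ValueError(f"invalid {col} values: {sorted(bad)}")
        if self.calls.size and self.calls.max() > 3:
            raise ValueError("calls must lie in {0, 1, 2, MISSING}")
        if "birth_year" in self.samples:
            yr = pd.to_numeric(self.samples["birth_year"], errors="coerce")
            ok = yr.isna() | ((yr >= 1900) & (yr <= 2100))
            if not ok.all():
                raise ValueError("birth_year outside plausible range 1900-2100")

    # -- subsetting --------------------------------------------------------

    def take_samples(self, index: np.ndarray) -> "GenotypeDataset":
        """Positional sample subset (order preserved as given)."""
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples.iloc[index], self.markers, self.calls[index, :]
        )

    def take_markers(self, index: np.ndarray) -> "GenotypeDataset":
        """Positional marker subset (order preserved as given)."""
        index = np.asarray(index)
        return GenotypeDataset(
            self.samples, self.markers.iloc[index], self.calls[:, index]
        )

    def sorted_by_position(self) -> "GenotypeDataset":
        order = np.lexsort(
            (self.markers["position_bp"].to_numpy(), self.markers["chromosome"])
        )
        if np.array_equal(order, np.arange(self.n_markers)):
            return self
        return self.take_markers(order)

    # -- per-marker summaries ---------------------------------------------

    def allele_freqs(self) -> np.ndarray:
        """Allele-A1 frequency per marker over non-missing calls (NaN if none)."""
        obs = self.calls != MISSING
        n_obs = obs.sum(axis=0)
        dose = np.where(obs, self.calls, 0).sum(axis=0, dtype=np.int64)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n_obs > 0, dose / (2.0 * n_obs), np.nan)

    def sample_call_rate(self) -> np.ndarray:
        if self.n_markers == 0:
            return np.ones(self.n_samples)
        return (self.calls != MISSING).mean(axis=1)

    def marker_call_rate(self) -> np.ndarray:
        if self.n_samples == 0:
            return np.ones(self.n_markers)
        return (self.calls != MISSING).mean(axis=0)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeDataset):
            return NotImplemented
        return (
            self.samples.equals(other.samples)
            and self.markers.equals(other.markers)
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary triplet
# ---------------------------------------------------------------------------


def read_plink_binary(prefix_path: str | Path) -> GenotypeDataset:
    """Read a PLINK 1 bed/bim/fam triplet (SNP-major) into a dataset.

    A sidecar metadata table ``<prefix>.samples.tsv`` with columns
    ``sample_id``, ``population``, ``birth_year`` is merged into the sample
    table when present; otherwise population defaults to the fam family ID
    and birth_year to missing.
    """
    prefix = Path(prefix_path)
    bed, bim, fam = (prefix.parent / (prefix.name + s) for s in (".bed", ".bim", ".fam"))
    for f in (bed, bim, fam):
        if not f.exists():
            raise FileNotFoundError(f"missing PLINK file: {f}")

    fam_df = pd.read_csv(
        fam,
        sep=r"\s+",
        header=None,
        names=["fid", "sample_id", "father", "mother", "sex_code", "phenotype"],
        dtype={"fid": str, "sample_id": str},
    )
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chromosome", "marker_id", "cm", "position_bp", "allele_a1", "allele_a2"],
        dtype={"chromosome": str, "marker_id": str, "allele_a1": str, "allele_a2": str},
    )

    n, m = len(fam_df), len(bim_df)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{bed}: bad magic bytes (expected PLINK 1 SNP-major)")
    bytes_per_marker = (n + 3) // 4
    expected = 3 + bytes_per_marker * m
    if len(raw) != expected:
        raise FormatError(
            f"{bed}: size {len(raw)} does not match {n} samples x {m} markers "
            f"(expected {expected})"
        )

    calls = np.empty((n, m), dtype=np.uint8)
    if m:
        body = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_marker)
        # unpack the four 2-bit fields of every byte, low bits first
        codes = np.empty((m, bytes_per_marker * 4), dtype=np.uint8)
        for k in range(4):
            codes[:, k::4] = (body >> (2 * k)) & 0b11
        calls[:] = _BED_TO_CALL[codes[:, :n]].T

    samples = pd.DataFrame(
        {
            "sample_id": fam_df["sample_id"],
            "population": fam_df["fid"],
            "birth_year": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )
    if fam_df["sex_code"].isin([1, 2]).any():
        samples["sex"] = fam_df["sex_code"].map({1: "M", 2: "F"})
    sidecar = prefix.parent / (prefix.name + ".samples.tsv")
    if sidecar.exists():
        meta = pd.read_csv(sidecar, sep="\t", dtype={"sample_id": str})
        meta["birth_year"] = pd.array(meta.get("birth_year"), dtype="Int64")
        keep = [c for c in ("population", "birth_year", "sex") if c in meta]
        samples = samples.drop(columns=keep).merge(
            meta[["sample_id", *keep]], on="sample_id", how="left", validate="1:1"
        )
        samples["birth_year"] = pd.array(samples["birth_year"], dtype="Int64")
    front = ["sample_id", "population", "birth_year"]
    samples = samples[front + [c for c in samples.columns if c not in front]]

    markers = bim_df[
        ["marker_id", "chromosome", "position_bp", "allele_a1", "allele_a2"]
    ]
    return GenotypeDataset(samples, markers, calls)


def write_plink_binary(ds: GenotypeDataset, prefix_path: str | Path) -> None:
    """Write ``ds`` as a PLINK 1 bed/bim/fam triplet plus metadata sidecar.

    Round-trips bit-exactly through :func:`read_plink_binary`.
    """
    prefix = Path(prefix_path)
    prefix.parent.mkdir(parents=True, exist_ok=True)

    n, m = ds.n_samples, ds.n_markers
    sex_code = (
        ds.samples["sex"].map({"M": 1, "F": 2}).fillna(0).astype(int)
        if "sex" in ds.samples
        else pd.Series(np.zeros(n, dtype=int))
    )
    fam = pd.DataFrame(
        {
            "fid": ds.samples.get("population", pd.Series(["0"] * n)).astype(str),
            "iid": ds.samples["sample_id"],
            "father": 0,
            "mother": 0,
            "sex": sex_code.to_numpy(),
            "phenotype": -9,
        }
    )
    fam.to_csv(prefix.parent / (prefix.name + ".fam"), sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chromosome": ds.markers["chromosome"],
            "marker_id": ds.markers["marker_id"],
            "cm": 0,
            "position_bp": ds.markers["position_bp"],
            "a1": ds.markers["allele_a1"],
            "a2": ds.markers["allele_a2"],
        }
    )
    bim.to_csv(prefix.parent / (prefix.name + ".bim"), sep="\t", header=False, index=False)

    bytes_per_marker = (n + 3) // 4
    codes = np.full((m, bytes_per_marker * 4), 1, dtype=np.uint8)  # pad = missing
    codes[:, :n] = _CALL_TO_BED[ds.calls.T]
    body = np.zeros((m, bytes_per_marker), dtype=np.uint8)
    for k in range(4):
        body |= codes[:, k::4] << (2 * k)
    (prefix.parent / (prefix.name + ".bed")).write_bytes(_BED_MAGIC + body.tobytes())

    meta_cols = ["sample_id", "population", "birth_year"]
    meta = ds.samples[[c for c in meta_cols if c in ds.samples]]
    meta.to_csv(prefix.parent / (prefix.name + ".samples.tsv"), sep="\t", index=False)


# ---------------------------------------------------------------------------
# Cross-population marker harmonization
# ---------------------------------------------------------------------------


def harmonize_and_intersect(
    datasets: list[GenotypeDataset],
    drop_ambiguous: bool = True,
) -> tuple[list[GenotypeDataset], pd.DataFrame]:
    """Restrict datasets to shared markers with a common A1/A2 orientation.

    The first dataset defines the reference orientation.  Markers whose
    alleles in another dataset are the reference pair swapped get their
    calls flipped 0<->2 (missing untouched); markers whose allele pairs
    cannot be reconciled are dropped everywhere.  Strand-ambiguous A/T and
    C/G markers are dropped by default because their gametic-phase sign is
    unresolvable across genotyping batches.

    Returns the harmonized datasets (marker order taken from the first
    dataset) and a report with per-dataset kept/flipped/dropped counts.
    """
    if len(datasets) < 2:
        raise ValueError("harmonization needs at least two datasets")

    common: set[str] | None = None
    for ds in datasets:
        ids = set(ds.markers["marker_id"])
        common = ids if common is None else common & ids
    if not common:
        raise ValueError("no markers shared by all datasets")

    ref = datasets[0]
    ref_rows = ref.markers.set_index("marker_id")
    ordered = [
        mid for mid in ref.markers["marker_id"] if mid in common
    ]

    keep_ids: list[str] = []
    ambiguous_dropped = 0
    for mid in ordered:
        a1 = str(ref_rows.at[mid, "allele_a1"])
        a2 = str(ref_rows.at[mid, "allele_a2"])
        if drop_ambiguous and (a1, a2) in _AMBIGUOUS_PAIRS:
            ambiguous_dropped += 1
        else:
            keep_ids.append(mid)

    out: list[GenotypeDataset] = []
    records: list[dict] = []
    # decide flip/drop per dataset, then take the intersection of survivors
    flip_masks: list[np.ndarray] = []
    unresolved: set[str] = set()
    for ds in datasets:
        rows = ds.markers.set_index("marker_id")
        flips = np.zeros(len(keep_ids), dtype=bool)
        for i, mid in enumerate(keep_ids):
            a1 = str(rows.at[mid, "allele_a1"])
            a2 = str(rows.at[mid, "allele_a2"])
            r1 = str(ref_rows.at[mid, "allele_a1"])
            r2 = str(ref_rows.at[mid, "allele_a2"])
            if (a1, a2) == (r1, r2):
                continue
            if (a1, a2) == (r2, r1):
                flips[i] = True
            else:
                unresolved.add(mid)
        flip_masks.append(flips)

    final_ids = [mid for mid in keep_ids if mid not in unresolved]
    final_mask = np.array([mid not in unresolved for mid in keep_ids], dtype=bool)

    for ds, flips in zip(datasets, flip_masks):
        loc = pd.Index(ds.markers["marker_id"]).get_indexer(final_ids)
        sub = ds.take_markers(loc)
        flip_here = flips[final_mask]
        if flip_here.any():
            cols = np.flatnonzero(flip_here)
            block = sub.calls[:, cols]
            nonmiss = block != MISSING
            block[nonmiss] = 2 - block[nonmiss]
            sub.calls[:, cols] = block
            mk = sub.markers.copy()
            mk.loc[mk.index[cols], ["allele_a1", "allele_a2"]] = mk.loc[
                mk.index[cols], ["allele_a2", "allele_a1"]
            ].to_numpy()
            sub = GenotypeDataset(sub.samples, mk, sub.calls)
        out.append(sub)
        records.append(
            {
                "n_input_markers": ds.n_markers,
                "n_kept": len(final_ids),
                "n_flipped": int(flip_here.sum()),
                "n_dropped_ambiguous": ambiguous_dropped,
                "n_dropped_unresolved": len(unresolved),
            }
        )
    report = pd.DataFrame(records)
    report.insert(0, "dataset", range(len(datasets)))
    return out, report
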