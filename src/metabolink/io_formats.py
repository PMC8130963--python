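"""Readers and writers for the interchange formats the scoring core consumes.

Canonical dialects (all TSV with a header row, UTF-8, '.' decimal separator,
except the strain mapping which is CSV and spectra which are MGF):

* ``strains.csv``        — first column the canonical strain id, remaining
                           columns aliases.
* ``bgcs.tsv``           — ``bgc_id  strain_id  product_type  structures``
                           (structures ';'-separated, may be empty).
* ``clustering.tsv``     — ``bgc_id  family_id`` (simplified gene-cluster
                           -family assignment; a best-effort reader accepts
                           the upstream clustering-file dialect with
                           ``BGC Name`` / ``Family Number`` headers).
* ``components.tsv``     — ``spectrum_id  component`` (molecular-network
                           component; component -1 denotes a singleton).
* ``spectra.mgf``        — one BEGIN IONS/END IONS block per spectrum.
* ``spectrum_strains.tsv`` — ``spectrum_id  strain_id``, one association
                           per row.
* ``fingerprints.tsv``   — ``structure_key  bits`` (bits as a 0/1 string).
* ``validated_links.tsv``— ``gcf_id  mf_id`` plus optional extra columns.
* score tables           — the column set produced by
                           :func:`metabolink.strain_correlation.score_all_links`.
"""

from __future__ import annotations

import csv
import hashlib
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyteomics import mgf as _mgf

from metabolink.core_model import (
    BGC,
    GCF,
    MolecularFamily,
    Spectrum,
    Strain,
    deduplicate_gcfs,
    derive_strain_sets,
)
from metabolink.iokr import FingerprintVector

__all__ = [
    "DatasetBundle",
    "read_mgf",
    "write_mgf",
    "read_bigscape_clustering",
    "read_gnps_components",
    "read_strain_mapping",
    "write_strain_mapping",
    "read_bgcs",
    "write_bgcs",
    "read_spectrum_strains",
    "write_spectrum_strains",
    "read_fingerprints",
    "write_fingerprints",
    "read_validated_links",
    "write_validated_links",
    "read_score_table",
    "write_score_table",
    "read_config",
    "load_bundle",
    "write_bundle",
]


# ---------------------------------------------------------------------------
# spectra (MGF)


def read_mgf(path) -> list[Spectrum]:
    """Read MS2 spectra from an MGF file.

    Spectrum ids come from SCANS, then TITLE, then a 1-based block index.
    Peaks are sorted by m/z on load.
    """
    spectra = []
    try:
        with _mgf.MGF(str(path)) as reader:
            for i, entry in enumerate(reader):
                params = entry.get("params", {})
                sid = str(
                    params.get("scans") or params.get("title") or f"spectrum_{i + 1}"
                )
                pepmass = params.get("pepmass", (0.0,))
                precursor = float(pepmass[0]) if pepmass and pepmass[0] else 0.0
                peaks = tuple(
                    zip(
                        entry["m/z array"].tolist(),
                        entry["intensity array"].tolist(),
                    )
                )
                spectra.append(
                    Spectrum(id=sid, peaks=peaks, precursor_mz=precursor)
                )
    except Exception as exc:  # pyteomics raises assorted parse errors
        raise ValueError(f"malformed MGF file {path}: {exc}") from exc
    return spectra


def write_mgf(spectra: Iterable[Spectrum], path) -> None:
    """Write spectra as MGF, one block per spectrum (SCANS carries the id)."""
    entries = [
        {
            "m/z array": [p[0] for p in s.peaks],
            "intensity array": [p[1] for p in s.peaks],
            "params": {"title": s.id, "scans": s.id, "pepmass": s.precursor_mz},
        }
        for s in spectra
    ]
    _mgf.write(entries, str(path), file_mode="w")


# ---------------------------------------------------------------------------
# clustering / components


_BIGSCAPE_BGC_COLS = ("bgc_id", "#bgc name", "bgc name")
_BIGSCAPE_FAM_COLS = ("family_id", "family number", "family")


def read_bigscape_clustering(path, prefix: str = "GCF_") -> list[GCF]:
    """Read gene-cluster-family assignments from a clustering TSV.

    Accepts the canonical two-column ``bgc_id  family_id`` dialect, or
    best-effort the upstream clustering-file headers (``BGC Name`` /
    ``Family Number``).  Families with identical member sets (as arise when
    hybrid clusters are clustered under several product classes) are
    deduplicated.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = {c.lower().strip(): c for c in df.columns}
    bgc_col = next((cols[c] for c in _BIGSCAPE_BGC_COLS if c in cols), None)
    fam_col = next((cols[c] for c in _BIGSCAPE_FAM_COLS if c in cols), None)
    if bgc_col is None or fam_col is None:
        raise ValueError(
            f"clustering file {path} lacks BGC/family columns; "
            f"found headers {list(df.columns)}"
        )
    members: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        fam = str(row[fam_col])
        fam_id = fam if fam.startswith(prefix) else f"{prefix}{fam}"
        members.setdefault(fam_id, set()).add(str(row[bgc_col]))
    gcfs = [GCF(id=fid, members=frozenset(m)) for fid, m in members.items()]
    return deduplicate_gcfs(gcfs)


def read_gnps_components(
    path,
    known_spectra: set[str] | None = None,
    prefix: str = "MF_",
) -> list[MolecularFamily]:
    """Read molecular families from a molecular-network component TSV.

    Canonical columns ``spectrum_id  component``; best-effort columns
    ``cluster index`` / ``componentindex`` are also accepted.  Component -1
    marks singletons, which each get their own family.  With
    ``known_spectra`` given, rows referencing unknown spectra are skipped
    with a single warning reporting the count; conflicting duplicate
    assignments are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.empty:
        return []
    cols = {c.lower().strip(): c for c in df.columns}
    spec_col = next(
        (cols[c] for c in ("spectrum_id", "cluster index", "cluster_index") if c in cols),
        None,
    )
    comp_col = next(
        (cols[c] for c in ("component", "componentindex", "component index") if c in cols),
        None,
    )
    if spec_col is None or comp_col is None:
        raise ValueError(
            f"component file {path} lacks spectrum/component columns; "
            f"found headers {list(df.columns)}"
        )
    assignment: dict[str, str] = {}
    skipped = 0
    for _, row in df.iterrows():
        sid, comp = str(row[spec_col]), str(row[comp_col])
        if known_spectra is not None and sid not in known_spectra:
            skipped += 1
            continue
        if sid in assignment and assignment[sid] != comp:
            raise ValueError(
                f"spectrum {sid!r} assigned to conflicting components "
                f"{assignment[sid]!r} and {comp!r}"
            )
        assignment[sid] = comp
    if skipped:
        warnings.warn(
            f"skipped {skipped} component rows referencing unknown spectra",
            stacklevel=2,
        )
    members: dict[str, set[str]] = {}
    for sid, comp in assignment.items():
        fam_id = f"{prefix}singleton_{sid}" if comp == "-1" else f"{prefix}{comp}"
        members.setdefault(fam_id, set()).add(sid)
    return sorted(
        (MolecularFamily(id=fid, members=frozenset(m)) for fid, m in members.items()),
        key=lambda mf: mf.id,
    )


# ---------------------------------------------------------------------------
# strains, BGCs, spectrum-strain associations


def read_strain_mapping(path) -> list[Strain]:
    """Read the strain alias table (CSV: canonical id, then aliases)."""
    strains = []
    claimed: dict[str, str] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh):
            row = [c.strip() for c in row if c.strip()]
            if not row:
                continue
            sid, aliases = row[0], row[1:]
            for key in [sid, *aliases]:
                if key in claimed and claimed[key] != sid:
                    raise ValueError(
                        f"identifier {key!r} claimed by both strains "
                        f"{claimed[key]!r} and {sid!r}"
                    )
                claimed[key] = sid
            strains.append(Strain(id=sid, aliases=frozenset(aliases)))
    return strains


def write_strain_mapping(strains: Iterable[Strain], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        for s in strains:
            writer.writerow([s.id, *sorted(s.aliases)])


def read_bgcs(path) -> list[BGC]:
    """Read BGC records: ``bgc_id  strain_id  product_type  structures``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    required = {"bgc_id", "strain_id"}
    if not required <= set(df.columns):
        raise ValueError(f"BGC table {path} needs columns {sorted(required)}")
    return [
        BGC(
            id=row["bgc_id"],
            strain=row["strain_id"],
            product_type=row.get("product_type", ""),
            candidate_structures=tuple(
                s for s in row.get("structures", "").split(";") if s
            ),
        )
        for _, row in df.iterrows()
    ]


def write_bgcs(bgcs: Iterable[BGC], path) -> None:
    pd.DataFrame(
        [
            {
                "bgc_id": b.id,
                "strain_id": b.strain,
                "product_type": b.product_type,
                "structures": ";".join(b.candidate_structures),
            }
            for b in bgcs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_spectrum_strains(path) -> dict[str, frozenset[str]]:
    """Read spectrum->strain associations (TSV: spectrum_id, strain_id)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"spectrum_id", "strain_id"} <= set(df.columns):
        raise ValueError(
            f"spectrum-strain table {path} needs columns spectrum_id, strain_id"
        )
    out: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["spectrum_id"], set()).add(row["strain_id"])
    return {k: frozenset(v) for k, v in out.items()}


def write_spectrum_strains(assoc: Mapping[str, Iterable[str]], path) -> None:
    rows = [
        {"spectrum_id": sid, "strain_id": st}
        for sid in sorted(assoc)
        for st in sorted(assoc[sid])
    ]
    pd.DataFrame(rows, columns=["spectrum_id", "strain_id"]).to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# fingerprints, validated links, score tables


def read_fingerprints(path) -> dict[str, FingerprintVector]:
    """Read precomputed fingerprints: ``structure_key  bits`` (0/1 string)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"structure_key", "bits"} <= set(df.columns):
        raise ValueError(
            f"fingerprint table {path} needs columns structure_key, bits"
        )
    out = {}
    for _, row in df.iterrows():
        out[row["structure_key"]] = FingerprintVector(
            bits=tuple(int(c) for c in row["bits"])
        )
    lengths = {len(fp) for fp in out.values()}
    if len(lengths) > 1:
        raise ValueError(f"inconsistent fingerprint lengths in {path}: {lengths}")
    return out


def write_fingerprints(table: Mapping[str, FingerprintVector], path) -> None:
    pd.DataFrame(
        [
            {"structure_key": k, "bits": "".join(map(str, fp.bits))}
            for k, fp in sorted(table.items())
        ]
    ).to_csv(path, sep="\t", index=False)


def read_validated_links(path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"gcf_id", "mf_id"} <= set(df.columns):
        raise ValueError(f"validated-link table {path} needs gcf_id, mf_id columns")
    return [(row["gcf_id"], row["mf_id"]) for _, row in df.iterrows()]


def write_validated_links(links: Iterable[tuple[str, str]], path) -> None:
    pd.DataFrame(links, columns=["gcf_id", "mf_id"]).to_csv(
        path, sep="\t", index=False
    )


def read_score_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_score_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_config(path) -> dict[str, str]:
    """Read a flat key=value configuration file ('#' comments allowed)."""
    out = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), 1
    ):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


# ---------------------------------------------------------------------------
# bundle


@dataclass
class DatasetBundle:
    """Everything one paired dataset contributes, with referential integrity.

    ``provenance`` maps each source file to its SHA-256 checksum when the
    bundle was loaded from disk.
    """

    strains: list[Strain]
    bgcs: list[BGC]
    gcfs: list[GCF]
    spectra: list[Spectrum]
    mfs: list[MolecularFamily]
    fingerprints: dict[str, FingerprintVector] | None = None
    validated_links: list[tuple[str, str]] | None = None
    provenance: dict[str, str] = field(default_factory=dict)

    def occurrence(self):
        """Derive the strain-occurrence data (validates all references)."""
        return derive_strain_sets(
            self.bgcs, self.gcfs, self.spectra, self.mfs, self.strains
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def load_bundle(directory) -> DatasetBundle:
    """Load a dataset from a directory of canonical files.

    Expects ``strains.csv``, ``bgcs.tsv``, ``clustering.tsv``,
    ``spectra.mgf``, ``spectrum_strains.tsv``, ``components.tsv``; optional
    ``fingerprints.tsv`` and ``validated_links.tsv``.  Referential integrity
    is checked by deriving the occurrence data.
    """
    d = Path(directory)
    provenance = {}

    def track(name: str) -> Path:
        p = d / name
        if p.exists():
            provenance[name] = _sha256(p)
        return p

    strains = read_strain_mapping(track("strains.csv"))
    bgcs = read_bgcs(track("bgcs.tsv"))
    gcfs = read_bigscape_clustering(track("clustering.tsv"))
    spectra = read_mgf(track("spectra.mgf"))
    assoc_path = track("spectrum_strains.tsv")
    if assoc_path.exists():
        assoc = read_spectrum_strains(assoc_path)
        spectra = [
            Spectrum(
                id=s.id,
                peaks=s.peaks,
                precursor_mz=s.precursor_mz,
                strain_set=assoc.get(s.id, frozenset()),
            )
            for s in spectra
        ]
    mfs = read_gnps_components(
        track("components.tsv"), known_spectra={s.id for s in spectra}
    )
    fp_path = track("fingerprints.tsv")
    fingerprints = read_fingerprints(fp_path) if fp_path.exists() else None
    vl_path = track("validated_links.tsv")
    validated = read_validated_links(vl_path) if vl_path.exists() else None

    bundle = DatasetBundle(
        strains=strains,
        bgcs=bgcs,
        gcfs=gcfs,
        spectra=spectra,
        mfs=mfs,
        fingerprints=fingerprints,
        validated_links=validated,
        provenance=provenance,
    )
    bundle.occurrence()  # referential-integrity check on load
    return bundle


def write_bundle(bundle: DatasetBundle, directory) -> None:
    """Write a dataset to a directory in the canonical dialects."""
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_strain_mapping(bundle.strains, d / "strains.csv")
    write_bgcs(bundle.bgcs, d / "bgcs.tsv")
    rows = [
        {"bgc_id": bid, "family_id": gcf.id}
        for gcf in bundle.gcfs
        for bid in sorted(gcf.members)
    ]
    pd.DataFrame(rows, columns=["bgc_id", "family_id"]).to_csv(
        d / "clustering.tsv", sep="\t", index=False
    )
    write_mgf(bundle.spectra, d / "spectra.mgf")
    write_spectrum_strains(
        {s.id: s.strain_set for s in bundle.spectra if s.strain_set},
        d / "spectrum_strains.tsv",
    )
    comp_rows = []
    for mf in bundle.mfs:
        comp = (
            "-1"
            if mf.id.startswith("MF_singleton_")
            else mf.id.removeprefix("MF_")
        )
        comp_rows.extend(
            {"spectrum_id": sid, "component": comp} for sid in sorted(mf.members)
        )
    pd.DataFrame(comp_rows, columns=["spectrum_id", "component"]).to_csv(
        d / "components.tsv", sep="\t", index=False
    )
    if bundle.fingerprints is not None:
        write_fingerprints(bundle.fingerprints, d / "fingerprints.tsv")
    if bundle.validated_links is not None:
        write_validated_links(bundle.validated_links, d / "validated_links.tsv")
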