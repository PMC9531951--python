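"""Reading and writing of force-distance curves, proteome tables and reports.

On-disk dialects
----------------
Curve files are headered TSV with two numeric columns, ``separation_nm`` (or
``piezo_nm`` when the abscissa is raw piezo position, i.e. tip deflection not
yet subtracted) and ``force_pN``.  Lines starting with ``#`` are metadata and
are ignored.  A batch can alternatively be described by a manifest CSV with
columns ``file,spring_constant_pN_per_nm,sample_id``.

Proteome tables are TSV with one row per protein:
``protein_id, n_residues, abundance, is_membrane, ss_class, final_domain_nm,
loop_centers_nm`` where ``loop_centers_nm`` is a semicolon-separated list of
loop-center positions on the unfolded-contour axis (may be empty).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

DEFAULT_SPRING_CONSTANT = 840.0  # pN/nm (0.84 N/m nominal cantilever)

VALID_SS_CLASSES = {"helix", "sheet", "mixed", "unknown"}


class SmfsIOError(IOError):
    """Unreadable or unwritable file."""


class ParseError(ValueError):
    """Malformed cell or row in an input table."""


class FormatError(ValueError):
    """Structurally invalid input (wrong columns, length mismatch...)."""


@dataclass
class ForceDistanceCurve:
    """A raw AFM retraction trace.

    ``z`` is the abscissa in nm (piezo position, or tip-sample separation when
    ``is_tss``), ``force`` the measured force in pN (pulling positive).
    """

    curve_id: str
    z: np.ndarray
    force: np.ndarray
    spring_constant: float = DEFAULT_SPRING_CONSTANT
    sample_id: str = ""
    is_tss: bool = False

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if self.z.ndim != 1 or self.force.ndim != 1:
            raise FormatError(f"{self.curve_id}: arrays must be 1-D")
        if len(self.z) != len(self.force):
            raise FormatError(
                f"{self.curve_id}: length mismatch "
                f"({len(self.z)} positions vs {len(self.force)} forces)"
            )
        if len(self.z) < 2:
            raise FormatError(f"{self.curve_id}: need at least 2 points")
        if not (np.all(np.isfinite(self.z)) and np.all(np.isfinite(self.force))):
            raise FormatError(f"{self.curve_id}: non-finite values")
        if not self.spring_constant > 0:
            raise FormatError(f"{self.curve_id}: spring_constant must be > 0")

    def __len__(self) -> int:
        return len(self.z)


@dataclass
class CurveSet:
    """Ordered collection of curves with unique ids."""

    curves: list[ForceDistanceCurve]
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [c.curve_id for c in self.curves]
        if len(set(ids)) != len(ids):
            dupes = {i for i in ids if ids.count(i) > 1}
            raise FormatError(f"duplicate curve ids: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.curves)

    def __iter__(self):
        return iter(self.curves)

    def __getitem__(self, i):
        return self.curves[i]

    @property
    def ids(self) -> list[str]:
        return [c.curve_id for c in self.curves]


@dataclass
class ProteinRecord:
    """One proteome-table row: identity, abundance and membrane topology.

    ``final_domain_nm`` is the length of the terminal soluble domain (0 when
    absent or unknown); ``loop_centers_nm`` are loop-center positions along
    the unfolded contour measured from the pulled terminus.
    """

    protein_id: str
    n_residues: int
    abundance: float
    is_membrane: int
    ss_class: str = "unknown"
    final_domain_nm: float = 0.0
    loop_centers_nm: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.n_residues <= 0:
            raise FormatError(f"{self.protein_id}: n_residues must be > 0")
        if self.abundance < 0:
            raise FormatError(f"{self.protein_id}: negative abundance")
        if self.is_membrane not in (0, 1):
            raise FormatError(f"{self.protein_id}: is_membrane must be 0 or 1")
        if self.ss_class not in VALID_SS_CLASSES:
            raise FormatError(
                f"{self.protein_id}: ss_class {self.ss_class!r} not in "
                f"{sorted(VALID_SS_CLASSES)}"
            )
        lmax = self.n_residues * 0.4
        for lc in self.loop_centers_nm:
            if not 0 <= lc <= lmax:
                raise FormatError(
                    f"{self.protein_id}: loop center {lc} nm outside [0, {lmax}]"
                )

    @property
    def contour_length_nm(self) -> float:
        """Nominal fully-stretched length, 0.4 nm per residue."""
        return self.n_residues * 0.4


# ---------------------------------------------------------------------------
# curve reading


def _read_curve_tsv(path: Path, spring_constant: float, sample_id: str) -> ForceDistanceCurve:
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except OSError as exc:
        raise SmfsIOError(f"cannot read {path}: {exc}") from exc
    except pd.errors.ParserError as exc:
        raise FormatError(f"{path}: {exc}") from exc

    cols = [c.strip() for c in df.columns]
    df.columns = cols
    if "separation_nm" in cols:
        zcol, is_tss = "separation_nm", True
    elif "piezo_nm" in cols:
        zcol, is_tss = "piezo_nm", False
    else:
        raise FormatError(
            f"{path}: expected a 'separation_nm' or 'piezo_nm' column, got {cols}"
        )
    if "force_pN" not in cols:
        raise FormatError(f"{path}: missing 'force_pN' column")

    z = pd.to_numeric(df[zcol], errors="coerce")
    f = pd.to_numeric(df["force_pN"], errors="coerce")
    for name, col in ((zcol, z), ("force_pN", f)):
        bad = col.index[col.isna() & df[name].notna()]
        if len(bad):
            # +2: header line plus 1-based row numbering
            raise ParseError(f"{path}: non-numeric {name!r} value at row {bad[0] + 2}")
    if z.isna().any() or f.isna().any():
        raise FormatError(f"{path}: missing values")
    return ForceDistanceCurve(
        curve_id=path.stem,
        z=z.to_numpy(),
        force=f.to_numpy(),
        spring_constant=spring_constant,
        sample_id=sample_id,
        is_tss=is_tss,
    )


def read_fd_curves(
    path: str | Path,
    dialect: str = "two_column_tsv",
    spring_constant: float = DEFAULT_SPRING_CONSTANT,
    sample_id: str = "",
) -> CurveSet:
    """Read a batch of F-D curves from a directory of TSV files or a manifest.

    Parameters
    ----------
    path : directory of ``*.tsv`` files, a single TSV file, or a manifest CSV
        (``dialect="manifest"``).
    dialect : {"two_column_tsv", "manifest"}
    spring_constant : default cantilever stiffness (pN/nm) for curves without
        a per-curve value.
    """
    path = Path(path)
    if dialect == "two_column_tsv":
        if path.is_dir():
            files = sorted(path.glob("*.tsv"))
        elif path.exists():
            files = [path]
        else:
            raise SmfsIOError(f"no such file or directory: {path}")
        curves = [_read_curve_tsv(p, spring_constant, sample_id) for p in files]
        return CurveSet(curves=curves, provenance=[str(path)])
    if dialect == "manifest":
        if not path.exists():
            raise SmfsIOError(f"no such manifest: {path}")
        man = pd.read_csv(path)
        if "file" not in man.columns:
            raise FormatError(f"{path}: manifest needs a 'file' column")
        curves = []
        for _, row in man.iterrows():
            fp = Path(row["file"])
            if not fp.is_absolute():
                fp = path.parent / fp
            k = row.get("spring_constant_pN_per_nm", np.nan)
            k = float(k) if np.isfinite(k) else spring_constant
            sid = str(row.get("sample_id", "") or "")
            curves.append(_read_curve_tsv(fp, k, sid))
        return CurveSet(curves=curves, provenance=[str(path)])
    raise ValueError(f"unknown dialect {dialect!r}")


def write_fd_curve(curve: ForceDistanceCurve, path: str | Path) -> None:
    """Write a curve in the canonical two-column TSV dialect."""
    path = Path(path)
    zcol = "separation_nm" if curve.is_tss else "piezo_nm"
    df = pd.DataFrame({zcol: curve.z, "force_pN": curve.force})
    with open(path, "w") as fh:
        fh.write(f"# curve_id={curve.curve_id}\n")
        fh.write(f"# spring_constant_pN_per_nm={curve.spring_constant}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.9g")


# ---------------------------------------------------------------------------
# proteome table

PROTEOME_COLUMNS = [
    "protein_id",
    "n_residues",
    "abundance",
    "is_membrane",
    "ss_class",
    "final_domain_nm",
    "loop_centers_nm",
]


def read_proteome_table(path: str | Path) -> list[ProteinRecord]:
    """Read a proteome TSV into a list of :class:`ProteinRecord` (row order kept)."""
    path = Path(path)
    if not path.exists():
        raise SmfsIOError(f"no such file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = set(PROTEOME_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    if df["protein_id"].duplicated().any():
        dupes = df.loc[df["protein_id"].duplicated(), "protein_id"].tolist()
        raise FormatError(f"{path}: duplicate protein_id {dupes}")
    records = []
    for idx, row in df.iterrows():
        loops_raw = row["loop_centers_nm"]
        if pd.isna(loops_raw) or str(loops_raw).strip() == "":
            loops: list[float] = []
        else:
            try:
                loops = [float(tok) for tok in str(loops_raw).split(";") if tok.strip()]
            except ValueError as exc:
                raise ParseError(f"{path}: bad loop list at row {idx + 2}") from exc
        try:
            rec = ProteinRecord(
                protein_id=str(row["protein_id"]),
                n_residues=int(float(row["n_residues"])),
                abundance=float(row["abundance"]),
                is_membrane=int(float(row["is_membrane"])),
                ss_class=str(row["ss_class"]),
                final_domain_nm=float(row["final_domain_nm"]),
                loop_centers_nm=loops,
            )
        except ValueError as exc:
            if isinstance(exc, FormatError):
                raise
            raise ParseError(f"{path}: non-numeric cell at row {idx + 2}") from exc
        records.append(rec)
    return records


def write_proteome_table(records: Sequence[ProteinRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "protein_id": r.protein_id,
                "n_residues": r.n_residues,
                "abundance": r.abundance,
                "is_membrane": r.is_membrane,
                "ss_class": r.ss_class,
                "final_domain_nm": r.final_domain_nm,
                "loop_centers_nm": ";".join(f"{x:g}" for x in r.loop_centers_nm),
            }
        )
    pd.DataFrame(rows, columns=PROTEOME_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result reports


def write_results(refined, posteriors, path: str | Path, config: dict | None = None) -> None:
    """Write cluster reports: member lists, summary, ranked candidates, config.

    Parameters
    ----------
    refined : RefinedClusters (see :mod:`smfsid.cluster_refinement`)
    posteriors : mapping cluster id -> PosteriorTable (may be empty)
    path : output directory (created if needed)
    config : optional run-configuration snapshot, dumped as JSON
    """
    outdir = Path(path)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise SmfsIOError(f"cannot create {outdir}: {exc}") from exc

    member_rows = []
    summary_rows = []
    for cid in sorted(refined.clusters):
        members = refined.clusters[cid]
        for m in members:
            member_rows.append({"cluster_id": cid, "trace_id": m})
        obs = refined.observables.get(cid)
        summary_rows.append(
            {
                "cluster_id": cid,
                "n_members": len(members),
                "lc_max_nm": getattr(obs, "lc_max", np.nan),
                "mean_force_pN": getattr(obs, "mean_force", np.nan),
            }
        )
    pd.DataFrame(member_rows, columns=["cluster_id", "trace_id"]).to_csv(
        outdir / "cluster_members.tsv", sep="\t", index=False
    )
    pd.DataFrame(
        summary_rows, columns=["cluster_id", "n_members", "lc_max_nm", "mean_force_pN"]
    ).to_csv(outdir / "cluster_summary.tsv", sep="\t", index=False)

    for cid, table in (posteriors or {}).items():
        df = table.to_frame() if hasattr(table, "to_frame") else pd.DataFrame(table)
        df.to_csv(outdir / f"candidates_{cid}.tsv", sep="\t", index=False)

    snap = dict(config or {})
    with open(outdir / "run_config.json", "w") as fh:
        json.dump(snap, fh, indent=2, sort_keys=True, default=str)


def read_cluster_members(path: str | Path) -> dict[str, list[str]]:
    """Inverse of the member-list report, for round-trip checks."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        out.setdefault(row["cluster_id"], []).append(row["trace_id"])
    return out
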