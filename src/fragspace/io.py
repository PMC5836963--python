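"""SMILES file reading and TSV output writers.

Input is the conventional ``.smi`` layout: one molecule per line as
``SMILES[TAB]ID``; a missing id is auto-assigned ``MOL<line>``.  Lines
that fail to parse, and multi-component lines (salts / mixtures), are
skipped with a diagnostic — salt stripping is preprocessing, not
fragmentation.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from pathlib import Path

from rdkit import Chem

from .fragmenter import AssembledFragment, MoleculeParseError, MoleculeRecord
from .library import CountSummary, FragmentLibrary, top_n

__all__ = [
    "ReadReport",
    "read_smiles_file",
    "read_smiles_text",
    "write_per_compound",
    "write_frequency",
    "write_summary",
]


@dataclass
class ReadReport:
    records: list[MoleculeRecord]
    diagnostics: list[str] = field(default_factory=list)

    @property
    def n_skipped(self) -> int:
        return len(self.diagnostics)


def read_smiles_text(text: str, source: str = "<text>") -> ReadReport:
    """Parse ``SMILES[TAB]ID`` lines; skip and log unusable lines."""
    records: list[MoleculeRecord] = []
    diags: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        smiles = parts[0].strip()
        cid = parts[1].strip() if len(parts) > 1 and parts[1].strip() else f"MOL{lineno}"
        probe = Chem.MolFromSmiles(smiles)
        if probe is not None and len(Chem.GetMolFrags(probe)) > 1:
            diags.append(
                f"{source}:{lineno}: skipped multi-component SMILES (salt/mixture?): {smiles}"
            )
            continue
        try:
            records.append(MoleculeRecord.from_smiles(smiles, cid))
        except MoleculeParseError as exc:
            diags.append(f"{source}:{lineno}: skipped: {exc}")
    return ReadReport(records=records, diagnostics=diags)


def read_smiles_file(path: str | Path) -> ReadReport:
    """Read a .smi file; missing file or zero parseable records is fatal."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    report = read_smiles_text(path.read_text(encoding="utf-8"), source=str(path))
    for d in report.diagnostics:
        print(d, file=sys.stderr)
    if not report.records:
        raise MoleculeParseError(f"{path}: no parseable molecules")
    return report


def write_per_compound(
    results: list[tuple[str, list[AssembledFragment]]], path: str | Path
) -> None:
    """One line per compound: ``ID<TAB>frag1 frag2 ...`` (space-joined)."""
    lines = [
        f"{cid}\t{' '.join(f.capped_smiles for f in frags)}" for cid, frags in results
    ]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_frequency(lib: FragmentLibrary, path: str | Path) -> None:
    """``canonical_smiles<TAB>frequency``, most frequent first."""
    ranked = top_n(lib, max(1, lib.unique_fragments)) if lib.freq else []
    lines = [f"{smi}\t{n}" for smi, n in ranked]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_summary(
    path: str | Path,
    ruleset_name: str,
    params_text: str,
    lib: FragmentLibrary,
    dist: CountSummary | None,
) -> None:
    """Single-row run summary (TSV with a header line)."""
    header = (
        "ruleset\tparams\tn_fragmented\tunique_fragments\t"
        "min\tq1\tmedian\tq3\tmax"
    )
    if dist is None:
        stats = "\t".join(["NA"] * 5)
    else:
        stats = f"{dist.min:g}\t{dist.q1:g}\t{dist.median:g}\t{dist.q3:g}\t{dist.max:g}"
    row = (
        f"{ruleset_name}\t{params_text}\t{lib.n_fragmented}\t"
        f"{lib.unique_fragments}\t{stats}"
    )
    Path(path).write_text(header + "\n" + row + "\n", encoding="utf-8")
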