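"""Readers and writers: FASTA, MGF, results/heat-map TSV, config, manifest."""
from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import __version__
from .chem import Peptide
from .scoring import SiteResult, Spectrum

__all__ = [
    "RunManifest",
    "read_fasta",
    "read_mgf",
    "write_mgf",
    "write_results",
    "read_results",
    "write_heatmap",
    "write_manifest",
    "annotate_sequence",
    "MgfParseError",
    "FastaParseError",
]

#: short labels used when rendering modified residues, e.g. oxM
MOD_LABELS = {"oxidation": "ox", "deamidation": "de", "carbamidomethyl": "cam"}


class FastaParseError(ValueError):
    pass


class MgfParseError(ValueError):
    pass


@dataclass
class RunManifest:
    inputs: Dict[str, str]
    config: Dict
    seed: int
    tool_version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))


def write_manifest(manifest: RunManifest, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "inputs": manifest.inputs,
                "config": manifest.config,
                "seed": manifest.seed,
                "tool_version": manifest.tool_version,
                "timestamp": manifest.timestamp,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_fasta(path) -> List[Tuple[str, str]]:
    """(protein_id, uppercase sequence) per record, in file order.

    The id is the first whitespace-delimited token of the description line;
    '*' stop characters are stripped with a warning.
    """
    records: List[Tuple[str, str]] = []
    header: Optional[str] = None
    chunks: List[str] = []

    def flush(line_no: int) -> None:
        nonlocal header, chunks
        if header is None:
            return
        seq = "".join(chunks).upper()
        if "*" in seq:
            warnings.warn(f"stripped '*' from record {header}")
            seq = seq.replace("*", "")
        records.append((header, seq))
        header, chunks = None, []

    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                header = line[1:].split()[0] if line[1:].split() else ""
                if not header:
                    raise FastaParseError(f"{path}:{line_no}: empty FASTA header")
            else:
                if header is None:
                    raise FastaParseError(
                        f"{path}:{line_no}: sequence data before first '>' header"
                    )
                chunks.append(line)
        flush(-1)
    if not records:
        warnings.warn(f"{path}: no FASTA records found")
    return records


def _parse_charge(value: str) -> int:
    value = value.strip().rstrip("+")
    if value.startswith("+"):
        value = value[1:]
    if value.endswith("-") or value.startswith("-"):
        raise MgfParseError(f"negative-mode charge {value!r} not supported")
    return int(value)


def read_mgf(path) -> List[Spectrum]:
    """Spectra from an MGF file; records lacking CHARGE are skipped with a warning."""
    spectra: List[Spectrum] = []
    in_block = False
    title: Optional[str] = None
    pepmass: Optional[float] = None
    charge: Optional[int] = None
    peaks: List[Tuple[float, float]] = []
    n_block = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if line == "BEGIN IONS":
                in_block = True
                n_block += 1
                title, pepmass, charge, peaks = None, None, None, []
                continue
            if line == "END IONS":
                if not in_block:
                    raise MgfParseError(f"{path}:{line_no}: END IONS without BEGIN IONS")
                in_block = False
                if pepmass is None:
                    raise MgfParseError(f"{path}:{line_no}: block without PEPMASS")
                if charge is None:
                    warnings.warn(
                        f"{path}: spectrum {title or n_block} lacks CHARGE; skipped"
                    )
                    continue
                spectra.append(
                    Spectrum(
                        scan_id=title or f"index={n_block}",
                        precursor_mz=pepmass,
                        precursor_charge=charge,
                        peaks=tuple(sorted(peaks)),
                    )
                )
                continue
            if not in_block:
                continue
            if "=" in line and not line[0].isdigit():
                key, _, value = line.partition("=")
                key = key.upper()
                if key == "TITLE":
                    title = value.strip()
                elif key == "PEPMASS":
                    pepmass = float(value.split()[0])
                elif key == "CHARGE":
                    charge = _parse_charge(value)
                continue
            fields = line.split()
            try:
                peak_mz, intensity = float(fields[0]), float(fields[1])
            except (IndexError, ValueError):
                raise MgfParseError(f"{path}:{line_no}: malformed peak line {line!r}") from None
            peaks.append((peak_mz, intensity))
    if in_block:
        raise MgfParseError(f"{path}: unterminated BEGIN IONS block")
    return spectra


def write_mgf(spectra: Sequence[Spectrum], path) -> None:
    with open(path, "w") as fh:
        for s in spectra:
            fh.write("BEGIN IONS\n")
            fh.write(f"TITLE={s.scan_id}\n")
            fh.write(f"PEPMASS={s.precursor_mz:.6f}\n")
            fh.write(f"CHARGE={s.precursor_charge}+\n")
            for peak_mz, intensity in s.peaks:
                fh.write(f"{peak_mz:.5f} {intensity:.3f}\n")
            fh.write("END IONS\n")


def annotate_sequence(p: Peptide, link_pos: int) -> str:
    """Render a peptide with '$1' after the cross-linked residue and short
    modification labels before modified residues (e.g. EGGK$1GPR, oxM)."""
    labels = {pos: MOD_LABELS.get(mod.name, mod.name + "-") for pos, mod in p.modifications}
    out = []
    for i, r in enumerate(p.sequence, start=1):
        out.append(labels.get(i, "") + r)
        if i == link_pos:
            out.append("$1")
    return "".join(out)


RESULT_COLUMNS = [
    "alpha_protein",
    "k_protein_pos",
    "beta_protein",
    "q_protein_pos",
    "alpha_peptide",
    "beta_peptide",
    "decoy_class",
    "n_spectra",
    "n_passing",
    "scan_ids",
    "best_score",
    "best_pp",
    "best_pp2",
    "best_pp_tag",
    "overall_score",
    "q_value",
    "accepted",
]


def write_results(sites: Sequence[SiteResult], path) -> None:
    """One TSV row per site, best-supported spectrum first."""
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for s in sites:
            alpha_seq = beta_seq = ""
            if s.spectra:
                pair = s.spectra[0].pair
                alpha_seq = annotate_sequence(pair.alpha, pair.k_pos)
                beta_seq = annotate_sequence(pair.beta, pair.q_pos)
            row = [
                s.alpha_protein,
                str(s.k_protein_pos),
                s.beta_protein,
                str(s.q_protein_pos),
                alpha_seq,
                beta_seq,
                s.decoy_class,
                str(len(s.spectra)),
                str(s.n_passing),
                ";".join(m.scan_id for m in s.spectra),
                f"{max((m.score for m in s.spectra), default=0.0):.2f}",
                f"{max((m.pp for m in s.spectra), default=0.0):.2f}",
                f"{max((m.pp2 for m in s.spectra), default=0.0):.2f}",
                f"{max((m.pp_tag for m in s.spectra), default=0.0):.2f}",
                f"{s.overall_score:.2f}",
                f"{s.q_value:.4f}",
                str(int(s.accepted)),
            ]
            fh.write("\t".join(row) + "\n")


def read_results(path) -> List[Dict[str, str]]:
    """Rows of a results TSV as dictionaries (round-trip of write_results)."""
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        return []
    header = lines[0].split("\t")
    return [dict(zip(header, ln.split("\t"))) for ln in lines[1:]]


def write_heatmap(
    matrix: np.ndarray,
    q_positions: Sequence[int],
    k_positions: Sequence[int],
    path,
) -> None:
    """Dense Q(rows) x K(columns) overall-score matrix as TSV."""
    with open(path, "w") as fh:
        fh.write("Q\\K\t" + "\t".join(f"K{k}" for k in k_positions) + "\n")
        for i, q in enumerate(q_positions):
            row = "\t".join(f"{matrix[i, j]:.2f}" for j in range(len(k_positions)))
            fh.write(f"Q{q}\t{row}\n")


def plot_heatmap(matrix, q_positions, k_positions, path) -> None:
    """Optional PNG rendering of the heat map (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(matrix, aspect="auto", cmap="viridis", origin="lower")
    ax.set_xlabel("K position")
    ax.set_ylabel("Q position")
    ax.set_xticks(range(len(k_positions)), [str(k) for k in k_positions], rotation=90, fontsize=6)
    ax.set_yticks(range(len(q_positions)), [str(q) for q in q_positions], fontsize=6)
    fig.colorbar(im, ax=ax, label="overall score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
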