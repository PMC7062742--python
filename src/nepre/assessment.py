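"""Decoy-set scoring and evaluation metrics.

Given a native structure and its decoys, every structure is scored under a
trained potential and sorted by energy (ascending; ties broken by name for
determinism).  The metrics mirror standard model-quality-assessment usage:
the native's energy rank, Top-N success counts over many sets, the lowest-
RMSD ("best") decoy and its rank, and the Pearson correlation between decoy
energy and CA RMSD to the native.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .errors import EmptyStructureError, PDBParseError
from .geometry import superpose_rmsd
from .potential import EnergyModel, score_structure
from .structure_io import ProteinChain, parse_pdb

logger = logging.getLogger(__name__)


@dataclass
class DecoyEntry:
    """One scored structure of a decoy set."""

    name: str
    path: str
    energy: float
    rmsd_to_native: float  # 0.0 for the native itself
    is_native: bool = False
    n_common_residues: int = 0
    suspicious_overlap: bool = False  # < 50% residue overlap with the native


@dataclass
class RankingReport:
    """Energy-sorted decoy-set report with native-recognition metrics."""

    entries: list[DecoyEntry]            # sorted by (energy, name)
    native_rank: int
    best_decoy_name: str | None
    best_decoy_rank: int | None
    pearson_r: float | None
    pearson_defined: bool
    skipped: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "rank": k + 1,
                "name": e.name,
                "energy": e.energy,
                "rmsd_to_native": e.rmsd_to_native,
                "is_native": e.is_native,
            }
            for k, e in enumerate(self.entries)
        ]
        return pd.DataFrame(rows)

    def to_json(self) -> str:
        payload = {
            "entries": [asdict(e) for e in self.entries],
            "native_rank": self.native_rank,
            "best_decoy_name": self.best_decoy_name,
            "best_decoy_rank": self.best_decoy_rank,
            "pearson_r": self.pearson_r,
            "pearson_defined": self.pearson_defined,
            "skipped": self.skipped,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "RankingReport":
        d = json.loads(text)
        return cls(
            entries=[DecoyEntry(**e) for e in d["entries"]],
            native_rank=d["native_rank"],
            best_decoy_name=d["best_decoy_name"],
            best_decoy_rank=d["best_decoy_rank"],
            pearson_r=d["pearson_r"],
            pearson_defined=d["pearson_defined"],
            skipped=d.get("skipped", []),
        )


def _common_ca(native: ProteinChain, other: ProteinChain) -> tuple[np.ndarray, np.ndarray]:
    ca_n = native.ca_coords()
    ca_o = other.ca_coords()
    common = sorted(set(ca_n) & set(ca_o))
    a = np.array([ca_n[k] for k in common], dtype=float).reshape(-1, 3)
    b = np.array([ca_o[k] for k in common], dtype=float).reshape(-1, 3)
    return a, b


def rmsd_to_native(native: ProteinChain, other: ProteinChain) -> tuple[float, int]:
    """CA RMSD over residues common to both chains, plus the overlap size."""
    a, b = _common_ca(native, other)
    if len(a) < 3:
        raise ValueError(f"only {len(a)} residues shared with the native; need >= 3 for RMSD")
    return superpose_rmsd(a, b), len(a)


def energy_rmsd_pearson(
    entries: Sequence[DecoyEntry], include_native: bool = False
) -> tuple[float | None, bool]:
    """Pearson r between energy and RMSD over a decoy set.

    The native (0-RMSD anchor) is excluded by default.  Returns
    ``(r, defined)``; zero variance in either variable or fewer than 3
    usable entries gives ``(None, False)`` rather than propagating NaN.
    """
    sel = [e for e in entries if include_native or not e.is_native]
    xs = np.array([e.energy for e in sel], dtype=float)
    ys = np.array([e.rmsd_to_native for e in sel], dtype=float)
    ok = np.isfinite(xs) & np.isfinite(ys)
    xs, ys = xs[ok], ys[ok]
    if len(xs) < 3 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None, False
    r = float(sp_stats.pearsonr(xs, ys).statistic)
    return r, True


def rank_structures(
    native: ProteinChain,
    native_name: str,
    decoys: Sequence[tuple[str, str, ProteinChain]],
    model: EnergyModel,
    include_native_in_pearson: bool = False,
) -> RankingReport:
    """Rank already-parsed structures (name, path, chain) against a native."""
    entries = [
        DecoyEntry(
            name=native_name,
            path="",
            energy=score_structure(native, model),
            rmsd_to_native=0.0,
            is_native=True,
            n_common_residues=len(native.residues),
        )
    ]
    skipped: list[str] = []
    for name, path, chain in decoys:
        try:
            rmsd, n_common = rmsd_to_native(native, chain)
        except ValueError as exc:
            logger.warning("skipping decoy %s: %s", name, exc)
            skipped.append(name)
            continue
        suspicious = n_common < 0.5 * len(native.residues)
        if suspicious:
            logger.warning("decoy %s shares only %d/%d residues with the native",
                           name, n_common, len(native.residues))
        entries.append(
            DecoyEntry(
                name=name,
                path=path,
                energy=score_structure(chain, model),
                rmsd_to_native=rmsd,
                is_native=False,
                n_common_residues=n_common,
                suspicious_overlap=suspicious,
            )
        )
    entries.sort(key=lambda e: (e.energy, e.name))
    native_rank = next(k + 1 for k, e in enumerate(entries) if e.is_native)
    non_native = [e for e in entries if not e.is_native]
    if non_native:
        best = min(non_native, key=lambda e: (e.rmsd_to_native, e.name))
        best_rank = next(k + 1 for k, e in enumerate(entries) if e.name == best.name)
        best_name = best.name
    else:
        best_name, best_rank = None, None
    r, defined = energy_rmsd_pearson(entries, include_native=include_native_in_pearson)
    return RankingReport(
        entries=entries,
        native_rank=native_rank,
        best_decoy_name=best_name,
        best_decoy_rank=best_rank,
        pearson_r=r,
        pearson_defined=defined,
        skipped=skipped,
    )


def rank_decoy_set(
    native: str | Path,
    decoys: Sequence[str | Path],
    model: EnergyModel,
    chain_selector: str | None = None,
    include_native_in_pearson: bool = False,
) -> RankingReport:
    """Score a native + decoy files and build the ranking report.

    Unparseable decoys are skipped with a warning and listed in the report;
    an unparseable native is fatal.
    """
    native_path = Path(native)
    native_chain = parse_pdb(native_path, chain_selector)[0]
    parsed: list[tuple[str, str, ProteinChain]] = []
    skipped: list[str] = []
    for p in decoys:
        p = Path(p)
        try:
            chain = parse_pdb(p, chain_selector)[0]
        except (PDBParseError, EmptyStructureError, FileNotFoundError) as exc:
            logger.warning("skipping decoy %s: %s", p.name, exc)
            skipped.append(p.stem)
            continue
        parsed.append((p.stem, str(p), chain))
    report = rank_structures(
        native_chain, native_path.stem, parsed, model,
        include_native_in_pearson=include_native_in_pearson,
    )
    report.skipped = skipped + report.skipped
    return report


def topn_success(reports: Sequence[RankingReport], n: int) -> int:
    """How many decoy sets have the native among the n lowest energies."""
    if n < 1:
        raise ValueError("n must be >= 1")
    return sum(1 for r in reports if r.native_rank <= n)
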