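"""Sequence input, result serialization, and the command-line interface.

Coordinates are 1-based inclusive everywhere a user sees them (flags,
output columns); conversion to 0-based happens once, inside the library.
Output files are deterministic: floats are fixed 6-decimal, candidate
order is the ranked order, and a provenance header echoes the resolved
configuration, so identical invocations produce byte-identical files.
"""

from __future__ import annotations

import difflib
import json
import logging
import os
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import click
from Bio import SeqIO

from . import __version__
from .errors import AmbiguousInputError, ShapemutError
from .design_core import (
    BASE_METRICS,
    CandidateResult,
    DistanceConfig,
    FocalRegion,
    MutationSpec,
    pareto_front,
    run_design,
)
from .seq_encoding import NucleotideSequence
from .shape_engine import (
    KmerShapeTable,
    feature_catalogue,
    read_kmer_table,
    synth_table,
)

logger = logging.getLogger("shapemut")


def read_sequence(source) -> NucleotideSequence:
    """Load a wild-type sequence from a literal string or a file path.

    An existing path is read as FASTA (exactly one record required); a file
    not starting with '>' is read as a bare sequence.  Anything else is
    treated as a literal sequence string.
    """
    if isinstance(source, Path) or (
        isinstance(source, str) and os.path.exists(source)
    ):
        text = Path(source).read_text(encoding="utf-8")
        if text.lstrip().startswith(">"):
            records = list(SeqIO.parse(str(source), "fasta"))
            if len(records) == 0:
                raise AmbiguousInputError(f"{source}: FASTA file holds no record")
            if len(records) > 1:
                raise AmbiguousInputError(
                    f"{source}: FASTA file holds {len(records)} records; "
                    "supply exactly one wild-type sequence"
                )
            return NucleotideSequence(str(records[0].seq))
        return NucleotideSequence("".join(text.split()))
    return NucleotideSequence(source)


@dataclass
class DesignRunConfig:
    """Fully-resolved run configuration, echoed into output headers."""

    sequence: str
    positions: Tuple[int, ...]
    focal: Optional[Tuple[int, ...]]
    features: Tuple[str, ...]
    shape_metric: str
    base_metric: str
    normalize: Optional[bool]
    predictor: str  # table path or "synthetic:<seed>"
    objective: str = "max"

    def header_items(self) -> List[Tuple[str, str]]:
        return [
            ("tool", f"shapemut {__version__}"),
            ("sequence", self.sequence),
            ("positions", ",".join(map(str, self.positions))),
            (
                "focal",
                "all" if self.focal is None else ",".join(map(str, self.focal)),
            ),
            ("features", ",".join(self.features)),
            ("shape_metric", self.shape_metric),
            ("base_metric", self.base_metric),
            (
                "normalize",
                "auto" if self.normalize is None else str(self.normalize).lower(),
            ),
            ("predictor", self.predictor),
            ("objective", self.objective),
        ]


_BASE_COLUMNS = ["sequence", "substitutions", "base_distance", "shape_distance"]


def _result_row(r: CandidateResult, features: Sequence[str]) -> List[str]:
    subs = ";".join(f"{p}:{a}>{b}" for p, a, b in r.substitutions) or "-"
    row = [
        r.sequence,
        subs,
        f"{r.base_distance:.6f}",
        f"{r.shape_distance:.6f}",
    ]
    row += [f"{r.feature_distances[f]:.6f}" for f in features]
    row += [str(int(r.is_wildtype)), str(r.rank)]
    return row


def write_results(
    results: Sequence[CandidateResult],
    cfg: DesignRunConfig,
    path,
    fmt: str = "tsv",
) -> None:
    """Write the ranked candidate table as TSV (default) or JSON.

    TSV carries a '#'-prefixed provenance header followed by one row per
    candidate; JSON mirrors the same content under "config" and
    "candidates" keys.  Floats are fixed 6-decimal in both dialects.
    """
    if not results:
        raise ValueError("no results to write")
    if fmt not in ("tsv", "json"):
        raise ValueError(f"format must be 'tsv' or 'json', got {fmt!r}")
    path = Path(path)
    features = list(cfg.features)
    if fmt == "tsv":
        cols = _BASE_COLUMNS + [f"shape_d_{f}" for f in features] + [
            "is_wildtype",
            "rank",
        ]
        lines = [f"# {k} = {v}" for k, v in cfg.header_items()]
        lines.append("\t".join(cols))
        lines += ["\t".join(_result_row(r, features)) for r in results]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    else:
        payload = {
            "config": dict(cfg.header_items()),
            "candidates": [
                {
                    "sequence": r.sequence,
                    "substitutions": [
                        {"position": p, "wt": a, "mut": b}
                        for p, a, b in r.substitutions
                    ],
                    "base_distance": round(r.base_distance, 6),
                    "shape_distance": round(r.shape_distance, 6),
                    "feature_distances": {
                        f: round(r.feature_distances[f], 6) for f in features
                    },
                    "is_wildtype": r.is_wildtype,
                    "rank": r.rank,
                }
                for r in results
            ],
        }
        path.write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )


def read_results(path) -> Tuple[Dict[str, str], List[CandidateResult]]:
    """Parse a TSV written by :func:`write_results` (round-trip for tests)."""
    header: Dict[str, str] = {}
    results: List[CandidateResult] = []
    cols: Optional[List[str]] = None
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        if line.startswith("#"):
            k, _, v = line[1:].partition("=")
            header[k.strip()] = v.strip()
            continue
        parts = line.split("\t")
        if cols is None:
            cols = parts
            continue
        rec = dict(zip(cols, parts))
        subs: List[Tuple[int, str, str]] = []
        if rec["substitutions"] != "-":
            for item in rec["substitutions"].split(";"):
                pos, _, change = item.partition(":")
                a, _, b = change.partition(">")
                subs.append((int(pos), a, b))
        fdist = {
            c[len("shape_d_"):]: float(rec[c])
            for c in cols
            if c.startswith("shape_d_")
        }
        results.append(
            CandidateResult(
                sequence=rec["sequence"],
                substitutions=tuple(subs),
                base_distance=float(rec["base_distance"]),
                shape_distance=float(rec["shape_distance"]),
                feature_distances=fdist,
                is_wildtype=bool(int(rec["is_wildtype"])),
                rank=int(rec["rank"]),
            )
        )
    return header, results


def _parse_positions(text: str, flag: str) -> List[int]:
    """Parse '3,5-7,12' into [3, 5, 6, 7, 12]."""
    out: List[int] = []
    for chunk in text.split(","):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "-" in chunk:
            lo, _, hi = chunk.partition("-")
            try:
                out.extend(range(int(lo), int(hi) + 1))
            except ValueError:
                raise click.UsageError(
                    f"{flag}: cannot parse range {chunk!r}"
                ) from None
        else:
            try:
                out.append(int(chunk))
            except ValueError:
                raise click.UsageError(
                    f"{flag}: cannot parse position {chunk!r}"
                ) from None
    if not out:
        raise click.UsageError(f"{flag}: no positions given")
    return out


def _resolve_features(names: Sequence[str]) -> Tuple[str, ...]:
    valid = [f.name for f in feature_catalogue()]
    resolved = []
    for raw in names:
        name = raw.strip()
        if name not in valid:
            hint = difflib.get_close_matches(name, valid, n=1)
            suggestion = f"; did you mean {hint[0]!r}?" if hint else ""
            raise click.UsageError(
                f"--features: unknown feature {name!r}{suggestion} "
                f"(valid: {', '.join(valid)})"
            )
        resolved.append(name)
    return tuple(resolved)


def _load_config_file(path: str) -> Dict[str, str]:
    """Flat 'key = value' config file; keys match the long flag names."""
    out: Dict[str, str] = {}
    for lineno, line in enumerate(
        Path(path).read_text(encoding="utf-8").splitlines(), start=1
    ):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise click.UsageError(
                f"--config {path}:{lineno}: expected 'key = value'"
            )
        k, _, v = line.partition("=")
        out[k.strip().replace("-", "_")] = v.strip()
    return out


@click.command(name="shapemut")
@click.option("--seq", help="Wild-type sequence: literal, or FASTA/plain file.")
@click.option(
    "--positions",
    help="Mutable positions, 1-based, comma list and/or ranges 'a-b' (max 7).",
)
@click.option(
    "--focal",
    default=None,
    help="Focal positions for shape distance (default: all positions).",
)
@click.option(
    "--features",
    default="MGW",
    show_default=True,
    help="Comma list of shape features.",
)
@click.option(
    "--shape-metric",
    type=click.Choice(["euclidean", "pearson"]),
    default="euclidean",
    show_default=True,
)
@click.option(
    "--base-metric",
    type=click.Choice(sorted(BASE_METRICS)),
    default="physchem",
    show_default=True,
)
@click.option(
    "--normalize/--no-normalize",
    "normalize",
    default=None,
    help="Z-score features over the candidate ensemble "
    "[default: on for >= 2 features].",
)
@click.option("--table", "table_path", default=None, help="k-mer table file.")
@click.option(
    "--synthetic-seed",
    type=int,
    default=None,
    help="Use a seeded synthetic pentamer table instead of --table.",
)
@click.option(
    "--objective",
    type=click.Choice(["max", "min"]),
    default="max",
    show_default=True,
    help="Rank by largest (max) or smallest (min) shape change.",
)
@click.option(
    "--pareto",
    type=click.Choice(["max", "min", "off"]),
    default="off",
    show_default=True,
    help="Also write the Pareto front (<out>.pareto.<fmt>).",
)
@click.option("--out", "out_path", help="Output file path.")
@click.option(
    "--format",
    "fmt",
    type=click.Choice(["tsv", "json"]),
    default="tsv",
    show_default=True,
)
@click.option("--config", "config_path", default=None, help="key = value file.")
@click.option(
    "--log-level",
    default="INFO",
    show_default=True,
    type=click.Choice(["DEBUG", "INFO", "WARNING", "ERROR"]),
)
@click.version_option(__version__)
def cli_main(
    seq,
    positions,
    focal,
    features,
    shape_metric,
    base_metric,
    normalize,
    table_path,
    synthetic_seed,
    objective,
    pareto,
    out_path,
    fmt,
    config_path,
    log_level,
):
    """Score all substitution candidates of a wild-type DNA sequence by base
    readout and shape readout, and write the ranked table."""
    t0 = time.monotonic()
    if config_path:
        file_cfg = _load_config_file(config_path)
        seq = seq or file_cfg.get("seq")
        positions = positions or file_cfg.get("positions")
        focal = focal or file_cfg.get("focal")
        out_path = out_path or file_cfg.get("out")
        table_path = table_path or file_cfg.get("table")
        if synthetic_seed is None and "synthetic_seed" in file_cfg:
            synthetic_seed = int(file_cfg["synthetic_seed"])
        if features == "MGW" and "features" in file_cfg:
            features = file_cfg["features"]
    logging.basicConfig(level=getattr(logging, log_level), format="%(message)s")
    if not seq:
        raise click.UsageError("--seq is required")
    if not positions:
        raise click.UsageError("--positions is required")
    if not out_path:
        raise click.UsageError("--out is required")
    if (table_path is None) == (synthetic_seed is None):
        raise click.UsageError(
            "exactly one of --table or --synthetic-seed is required"
        )
    feature_names = _resolve_features(features.split(","))
    try:
        wt = read_sequence(seq)
        spec = MutationSpec(_parse_positions(positions, "--positions"))
        spec.validate(len(wt))
        focal_region = None
        if focal is not None:
            focal_region = FocalRegion(_parse_positions(focal, "--focal"))
            focal_region.validate(len(wt))
        if table_path is not None:
            predictor: KmerShapeTable = read_kmer_table(table_path)
            predictor_desc = str(table_path)
        else:
            predictor = synth_table(5, feature_names, synthetic_seed)
            predictor_desc = f"synthetic:{synthetic_seed}"
        dcfg = DistanceConfig(
            features=feature_names,
            shape_metric=shape_metric,
            base_metric=base_metric,
            focal=focal_region,
            normalize=normalize,
        )
        rank_objective = pareto if pareto != "off" else objective
        results = run_design(wt, spec, dcfg, predictor, objective=rank_objective)
        run_cfg = DesignRunConfig(
            sequence=str(wt),
            positions=spec.positions,
            focal=None if focal_region is None else focal_region.positions,
            features=feature_names,
            shape_metric=shape_metric,
            base_metric=base_metric,
            normalize=normalize,
            predictor=predictor_desc,
            objective=rank_objective,
        )
        write_results(results, run_cfg, out_path, fmt=fmt)
        if pareto != "off":
            front = pareto_front(results, objective=pareto)
            p = Path(out_path)
            write_results(
                front, run_cfg, p.with_name(p.stem + f".pareto.{fmt}"), fmt=fmt
            )
    except ShapemutError as e:
        raise click.UsageError(str(e)) from e
    logger.info(
        "scored %d candidates (%s base metric, %s shape metric over %s) "
        "in %.2f s -> %s",
        len(results),
        base_metric,
        shape_metric,
        ",".join(feature_names),
        time.monotonic() - t0,
        out_path,
    )
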