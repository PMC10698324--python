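"""Readers and writers for the pipeline's file formats, plus run configuration.

All tabular outputs are TSV with one header line, "." for missing values, and
leading comment lines (``# key: value``) carrying the config hash and seed so
every file is traceable to the run that produced it.  The only non-TSV format
is the flat GP-map id array (.npy) with a JSON sidecar.
"""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .core import UNFOLDED, ComparisonResult, PredictorScores, TransitionRow
from .gpmap import GPMapTable
from .lattice import (ContactSet, LatticeConformation, StructureCatalogue,
                      build_catalogue)

MISSING = "."


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run byte-for-byte."""

    width: int = 5
    height: int = 5
    kBT: float = 0.5
    k: int = 30
    seed: int = 1
    pqp_mode: str = "exact"
    pqp_n: int = 1000
    distinguish_reversal: bool = True
    subopt_window: float = 0.02
    ensemble_cutoff: float = 15.0
    out_dir: str = "boltzmap_out"

    def hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # where outputs land does not change what they are
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text)
        return cls(**data)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def _header(config: RunConfig | None, seed: int | None = None) -> str:
    lines = []
    if config is not None:
        lines.append(f"# config_hash: {config.hash()}")
    if seed is not None or config is not None:
        lines.append(f"# seed: {seed if seed is not None else config.seed}")
    return "".join(line + "\n" for line in lines)


def _write_tsv(df: pd.DataFrame, path: str | Path,
               config: RunConfig | None = None, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(_header(config, seed))
        df.to_csv(fh, sep="\t", index=False, na_rep=MISSING)


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", na_values=[MISSING])


# ---------------------------------------------------------------------------
# structure catalogue

def write_catalogue(cat: StructureCatalogue, path: str | Path,
                    config: RunConfig | None = None) -> None:
    rows = []
    for conf, cs in zip(cat.conformations, cat.contact_sets):
        rows.append({
            "id": conf.canonical_id,
            "moves": conf.moves,
            "orbit_size": conf.orbit_size,
            "contacts": ";".join(f"{i}-{j}" for i, j in cs),
        })
    _write_tsv(pd.DataFrame(rows), path, config)


def read_catalogue(path: str | Path, width: int, height: int,
                   distinguish_reversal: bool = True) -> StructureCatalogue:
    df = _read_tsv(path)
    confs, contact_sets = [], []
    for _, row in df.sort_values("id").iterrows():
        confs.append(LatticeConformation.from_moves(
            row["moves"], canonical_id=int(row["id"]),
            orbit_size=int(row["orbit_size"])))
        pairs = frozenset()
        if isinstance(row["contacts"], str) and row["contacts"]:
            pairs = frozenset(tuple(map(int, p.split("-"))) for p in row["contacts"].split(";"))
        contact_sets.append(ContactSet(pairs))
    return StructureCatalogue(width, height, distinguish_reversal, confs, contact_sets)


# ---------------------------------------------------------------------------
# GP map (flat id array + JSON sidecar)

def save_gpmap(gp: GPMapTable, path: str | Path, catalogue_checksum: str = "",
               extra_meta: Mapping[str, Any] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, gp.assignment.astype(np.int32))
    meta = {
        "L": gp.L,
        "alphabet": list(gp.alphabet),
        "n_phenotypes": gp.n_phenotypes,
        "provenance": gp.provenance,
        "catalogue_checksum": catalogue_checksum,
        "sha256": hashlib.sha256(gp.assignment.astype(np.int32).tobytes()).hexdigest(),
        # the HP ensemble convention adopted throughout: compact states only
        "ensemble_states": "compact catalogue only",
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_gpmap(path: str | Path) -> GPMapTable:
    path = Path(path)
    arr = np.load(path if path.suffix == ".npy" else path.with_suffix(".npy"))
    meta = json.loads(path.with_suffix(".json").read_text())
    if hashlib.sha256(arr.astype(np.int32).tobytes()).hexdigest() != meta["sha256"]:
        raise IOError(f"GP map checksum mismatch for {path}")
    return GPMapTable(assignment=arr, L=meta["L"], alphabet=tuple(meta["alphabet"]),
                      n_phenotypes=meta["n_phenotypes"], provenance=meta["provenance"])


def catalogue_checksum(cat: StructureCatalogue) -> str:
    payload = "\n".join(c.moves for c in cat.conformations)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# phi tables and predictor scores

def write_phi_rows(rows: Iterable[TransitionRow], path: str | Path,
                   config: RunConfig | None = None) -> None:
    records = []
    for row in rows:
        denom = row.x * row.y
        for q, phi in sorted(row.phi.items(), key=lambda t: (t[0] == UNFOLDED, t[0])):
            records.append({
                "p_id": row.p,
                "q_id": q,
                "count": row.counts.get(q) if row.counts else None,
                "denominator": denom,
                "phi": phi,
            })
    _write_tsv(pd.DataFrame(records), path, config)


def read_phi_rows(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_scores(scores_list: Iterable[PredictorScores], path: str | Path,
                 config: RunConfig | None = None) -> None:
    records = []
    for sc in scores_list:
        for q, v in sorted(sc.scores.items(), key=lambda t: str(t[0])):
            records.append({
                "kind": sc.kind,
                "p_id": sc.context if sc.context is not None else MISSING,
                "q_id": q,
                "score": v,
                "n": sc.sample_size if sc.sample_size is not None else MISSING,
                "seed": sc.seed if sc.seed is not None else MISSING,
            })
    _write_tsv(pd.DataFrame(records), path, config)


def write_comparison(results: Iterable[ComparisonResult], path: str | Path,
                     config: RunConfig | None = None) -> None:
    records = [{
        "p": r.p, "k": r.k,
        "captured_fq": r.captured_fq, "captured_pqp": r.captured_pqp,
        "pearson_fq": r.pearson_fq, "pearson_pqp": r.pearson_pqp,
        "n_pairs_fq": r.n_pairs_fq, "n_pairs_pqp": r.n_pairs_pqp,
    } for r in results]
    _write_tsv(pd.DataFrame(records), path, config)


def write_sequence_sample(sample: Iterable[str], path: str | Path,
                          sidecar: Mapping[str, Any] | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("".join(s + "\n" for s in sample))
    if sidecar is not None:
        path.with_suffix(".json").write_text(json.dumps(dict(sidecar), indent=1))


def read_sequences(path: str | Path) -> list[str]:
    """One-per-line or FASTA sequence lists."""
    lines = Path(path).read_text().splitlines()
    if any(line.startswith(">") for line in lines):
        seqs, cur = [], []
        for line in lines:
            if line.startswith(">"):
                if cur:
                    seqs.append("".join(cur))
                cur = []
            elif line.strip():
                cur.append(line.strip())
        if cur:
            seqs.append("".join(cur))
        return seqs
    return [line.strip() for line in lines if line.strip() and not line.startswith("#")]


def read_subopt_fixture(path: str | Path) -> dict[str, list[tuple[str, float]]]:
    """Suboptimal-structure fixture TSV: sequence, dotbracket, energy_kcal_mol."""
    df = _read_tsv(path)
    table: dict[str, list[tuple[str, float]]] = {}
    for _, row in df.iterrows():
        table.setdefault(row["sequence"], []).append(
            (row["dotbracket"], float(row["energy_kcal_mol"])))
    return table


# ---------------------------------------------------------------------------
# pipeline orchestration

def run_pipeline(config: RunConfig) -> Path:
    """Run catalogue -> GP map -> phi -> predictors -> comparison, writing TSVs.

    Each stage's output lands in config.out_dir together with a manifest
    recording parameters, seeds and wall time; a stage failure aborts with the
    stage name while earlier outputs are preserved.
    """
    from .boltzmann_stats import pq_exact
    from .compare import compare_all
    from .gpmap import build_full_gpmap, phenotypic_frequencies, phi_row

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"config": asdict(config),
                                "config_hash": config.hash(), "stages": []}
    stage = "catalogue"
    try:
        t0 = time.time()
        cat = build_catalogue(config.width, config.height,
                              config.distinguish_reversal)
        write_catalogue(cat, out / "catalogue.tsv", config)
        manifest["stages"].append({"stage": stage, "n_structures": cat.n,
                                   "seconds": round(time.time() - t0, 3)})

        stage = "gpmap"
        t0 = time.time()
        gp = build_full_gpmap(cat)
        save_gpmap(gp, out / "gpmap.npy", catalogue_checksum(cat))
        manifest["stages"].append({
            "stage": stage,
            "n_sequences": gp.n_sequences,
            "n_catalogue_structures": cat.n,
            "n_folding_structures": int(len(gp.folding_phenotypes())),
            "seconds": round(time.time() - t0, 3)})

        stage = "phi"
        t0 = time.time()
        rows = [phi_row(gp, int(p)) for p in gp.folding_phenotypes()]
        write_phi_rows(rows, out / "phi.tsv", config)
        manifest["stages"].append({"stage": stage, "n_rows": len(rows),
                                   "seconds": round(time.time() - t0, 3)})

        stage = "predictors"
        t0 = time.time()
        fq = phenotypic_frequencies(gp)
        pq = pq_exact(gp, cat, config.kBT)
        write_scores([fq, pq], out / "scores.tsv", config)
        manifest["stages"].append({"stage": stage,
                                   "seconds": round(time.time() - t0, 3)})

        stage = "compare"
        t0 = time.time()
        results = compare_all(gp, cat, config.kBT, k=config.k,
                              pqp_mode=config.pqp_mode, pqp_n=config.pqp_n,
                              seed=config.seed)
        write_comparison(results, out / "comparison.tsv", config)
        manifest["stages"].append({"stage": stage, "n_results": len(results),
                                   "seconds": round(time.time() - t0, 3)})
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    config.dump(out / "config.yaml")
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return out
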