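"""TSV report writers and the run manifest.

All reports are tab-separated with '#'-prefixed metadata lines; percents and
ratios are printed to 2 dp, rates in scientific notation at 2 significant
figures, so report diffs stay meaningful.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

from . import __version__
from .snp_analysis import SnpSite
from .structural_analysis import StructuralEvent


def _write_tsv(df: pd.DataFrame, path: Path, meta: dict | None = None,
               index: bool = True) -> None:
    with open(path, "w") as fh:
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_sites(sites: list[SnpSite], path: Path) -> None:
    rows = []
    for s in sites:
        rows.append({
            "column": s.column + 1,  # reports are 1-based inclusive
            "alleles": "/".join(s.ingroup_alleles),
            "allelism": s.allelism,
            "rank": s.rank, "side": s.side, "branch": s.branch,
            "parallel": s.parallel,
            "ancestral": s.ancestral, "derived": s.derived,
            "direction_known": s.direction_known,
            "class": s.directed_class, "ts_tv": s.ts_tv,
            "region": s.region, "gene": s.gene,
            "effect": s.coding_effect,
        })
    _write_tsv(pd.DataFrame(rows), path, {"rows": len(rows)}, index=False)


def write_events(events: list[StructuralEvent], path: Path) -> None:
    rows = []
    for e in events:
        rows.append({
            "start": e.columns[0] + 1, "end": e.columns[1],
            "category": e.category, "length": e.length,
            "rank": e.rank, "side": e.side, "branch": e.branch,
            "direction": e.direction,
            "location": e.location, "locus": e.locus,
            "carriers": ",".join(e.carriers),
            "motif": e.motif, "loop": e.loop_length, "stem": e.stem_length,
            "flag": e.flag,
        })
    _write_tsv(pd.DataFrame(rows), path, {"rows": len(rows)}, index=False)


def format_rate(mu: float) -> str:
    return f"{mu:.2e}"


def write_rates(rates: pd.DataFrame, path: Path) -> None:
    df = rates.copy()
    for col in ("mu", "se"):
        if col in df:
            df[col] = df[col].map(format_rate)
    if "T_My" in df:
        df["T_My"] = df["T_My"].round(2)
    _write_tsv(df, path, index=False)


def sha256_of(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(path: Path, inputs: dict, params: dict,
                   outputs: list[str], complete: bool = True) -> None:
    import numpy, scipy, pandas
    manifest = {
        "plastmut_version": __version__,
        "library_versions": {
            "numpy": numpy.__version__, "scipy": scipy.__version__,
            "pandas": pandas.__version__,
        },
        "inputs": {k: {"path": str(v), "sha256": sha256_of(v)}
                   for k, v in inputs.items()},
        "parameters": params,
        "outputs": outputs,
        "complete": complete,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
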