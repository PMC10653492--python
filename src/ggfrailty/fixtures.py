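"""Synthetic life-table fixture generation with recorded provenance.

Stands in for credentialed mortality-database downloads: a cohort is
simulated from known parameters, aggregated into a life table, and written
in the CSV or HMD text dialect together with a JSON sidecar recording the
true parameters and the seed, so fixtures are byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

from .hmd import write_csv_table, write_hmd_pair
from .models import ThetaGG
from .simulation import build_life_table, sample_lifespans

__all__ = ["generate_fixture"]


def generate_fixture(
    theta_true: ThetaGG,
    n: int,
    start_age: int = 0,
    format: str = "csv",
    seed: int = 0,
    out_path="fixture",
) -> dict:
    """Simulate a cohort and write it as a life-table fixture.

    ``format='csv'`` writes ``<out_path>.csv``; ``format='hmd'`` writes
    ``<out_path>_deaths.txt`` and ``<out_path>_exposures.txt``.  Both also
    write ``<out_path>.meta.json`` with theta_true, n, start_age, seed and
    the list of files.  Returns the metadata dict.
    """
    if format not in ("csv", "hmd"):
        raise ValueError("format must be 'csv' or 'hmd'")
    out = Path(out_path)
    out.parent.mkdir(parents=True, exist_ok=True)
    lifespans = sample_lifespans(n, theta_true, seed)
    lt = build_life_table(lifespans, start_age=start_age)
    if format == "csv":
        files = [out.with_suffix(".csv")]
        write_csv_table(lt, files[0])
    else:
        files = [
            out.parent / f"{out.name}_deaths.txt",
            out.parent / f"{out.name}_exposures.txt",
        ]
        write_hmd_pair(lt, files[0], files[1])
    meta = {
        "synthetic": True,
        "theta_true": {"a": theta_true.a, "b": theta_true.b, "sigma2": theta_true.sigma2},
        "n": int(n),
        "start_age": int(start_age),
        "seed": int(seed),
        "format": format,
        "files": [f.name for f in files],
    }
    meta_path = out.parent / f"{out.name}.meta.json"
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return meta
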