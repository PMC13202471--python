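#!/usr/bin/env python
"""Generate the synthetic raw-data bundle for both nanoparticle families.

Writes scan images (TIFF + ground-truth JSON sidecars), saturation sweeps
and bleaching time traces (CSV) for dFONs(1)- and dFONs(2)-like particles
under the study's instrument settings, into scratch/data/.  Everything is
seeded; re-running reproduces the bundle byte for byte.
"""

import sys
from pathlib import Path

from click.testing import CliRunner

from dfon2p.cli import main as cli

OUT = Path(__file__).resolve().parents[1] / "scratch" / "data"

if __name__ == "__main__":
    seed = sys.argv[1] if len(sys.argv) > 1 else "1"
    result = CliRunner().invoke(
        cli, ["simulate", "--out", str(OUT), "--seed", seed],
        catch_exceptions=False,
    )
    n_csv = len(list(OUT.glob("*.csv")))
    n_tif = len(list(OUT.glob("*.tif")))
    print(f"wrote {n_tif} scans and {n_csv} trace CSVs to {OUT} (seed {seed})")
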