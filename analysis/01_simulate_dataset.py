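#!/usr/bin/env python
"""Generate the synthetic study dataset with known ground truth.

Writes a fixture directory under results/fixture/: genome table, true
domain BEDs per mark, gene BED, per-replicate CUT&RUN count bedGraphs with
spike-in counts, TPM/DE tables, TE-family RPKM, and a truth sidecar JSON.
Everything downstream (02-05) consumes these files.
"""

import sys
from pathlib import Path

from click.testing import CliRunner

from ladkit.cli import cli

OUT = Path(__file__).resolve().parent.parent / "results" / "fixture"
SEED = 20_240_101 % (2**31)


def main() -> None:
    runner = CliRunner()
    r = runner.invoke(cli, ["simulate", "--seed", str(SEED),
                            "--outdir", str(OUT)])
    if r.exit_code != 0:
        print(r.output, file=sys.stderr)
        raise SystemExit(r.exit_code)
    print(r.output.strip())
    n_files = len(list(OUT.iterdir()))
    print(f"fixture contains {n_files} files; truth sidecar: truth.json")


if __name__ == "__main__":
    main()
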