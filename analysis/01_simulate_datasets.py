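#!/usr/bin/env python
"""Generate the synthetic study datasets used by the downstream analyses.

Four transport 'genotypes' are simulated under the in-vivo imaging
protocol (20 µm segment, 100 frames / 426 s). The two mutant genotypes
halve the insertion rates but keep the speed distributions — the
flux-not-velocity phenotype — so the later analyses should recover
reduced flux at unchanged velocity. Arena movies for the locomotion assay
are generated by 03_locomotion.py on the fly.

Stacks (binary TIFF) go to scratch/; truth summaries (CSV/JSON) to results/.
"""

import json
import zlib
from pathlib import Path

from axotrace import io
from axotrace import synthetic_data as sd

GENOTYPES = {
    # label: (antero rate /min, retro rate /min)
    "control": (1.2, 0.8),
    "khc_wt": (1.15, 0.78),
    "khc_N262S": (0.6, 0.4),
    "khc_wt_N262S": (0.65, 0.42),
}
N_MOVIES = 10

scratch = Path("scratch/transport")
results = Path("results")
scratch.mkdir(parents=True, exist_ok=True)
results.mkdir(exist_ok=True)

manifest = {}
for g, (ra, rr) in GENOTYPES.items():
    movies = []
    for i in range(N_MOVIES):
        spec = sd.TransportSimSpec(antero_rate=ra, retro_rate=rr,
                                   noise_sd=2.0, n_stationary=0,
                                   seed=zlib.crc32(f"{g}_{i}".encode()))
        truth = sd.simulate_transport(spec)
        stack = sd.render_nerve_stack(truth)
        base = scratch / f"{g}_{i:02d}"
        io.write_stack(stack, base.with_suffix(".tif"))
        io.write_truth_json(truth, base.with_name(base.name + "_truth.json"))
        movies.append({
            "stack": str(base.with_suffix(".tif")),
            "truth": str(base.with_name(base.name + "_truth.json")),
            "antero_rate": ra, "retro_rate": rr, "seed": spec.seed,
        })
    manifest[g] = movies
    print(f"{g}: {N_MOVIES} movies at rates {ra}/{rr} per min")

(results / "transport_manifest.json").write_text(json.dumps(manifest, indent=1))
print(f"manifest -> {results/'transport_manifest.json'}")
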