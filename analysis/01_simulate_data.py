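#!/usr/bin/env python
"""Generate the synthetic study inputs.

Writes a severity ladder of compound-eye images (jitter and dropout sweeps)
to scratch/eyes/, a 500-gene weighted network with a 15-gene planted module
to results/synthetic/, and a genome-scale annotated universe with an
enriched candidate set.  Every downstream driver consumes these files.
"""

import argparse
from pathlib import Path

import pandas as pd
import tifffile

from quantkit._util import derive_seed
from quantkit.synthetic_data import (
    LatticeSpec,
    NetworkSpec,
    UniverseSpec,
    generate_eye_image,
    generate_network,
    generate_universe,
    write_edges_tsv,
    write_gene_list,
    write_universe_tsv,
)

ROOT = Path(__file__).resolve().parents[1]
JITTERS = (0.0, 1.0, 2.0, 4.0)
DROPOUTS = (0.0, 0.05, 0.1)
SEEDS_PER_CONDITION = 20


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()

    eye_dir = ROOT / "scratch" / "eyes"
    eye_dir.mkdir(parents=True, exist_ok=True)
    out_dir = ROOT / "results" / "synthetic"
    out_dir.mkdir(parents=True, exist_ok=True)

    records = []
    for kind, values in (("jitter", JITTERS), ("dropout", DROPOUTS)):
        for level in values:
            for rep in range(SEEDS_PER_CONDITION):
                sub = derive_seed(args.seed, f"{kind}:{level}:{rep}")
                spec = LatticeSpec(
                    jitter_sigma=level if kind == "jitter" else 0.0,
                    dropout_fraction=level if kind == "dropout" else 0.0,
                    seed=sub,
                )
                image, centers = generate_eye_image(spec)
                name = f"eye_{kind}{level:g}_{rep:02d}.tiff"
                tifffile.imwrite(eye_dir / name, image.pixels)
                records.append(
                    {"file": name, "condition": kind, "level": level,
                     "true_centers": centers.shape[0]}
                )
    manifest = pd.DataFrame(records)
    manifest.to_csv(out_dir / "eye_image_manifest.tsv", sep="\t", index=False)
    print(f"wrote {len(manifest)} eye images -> {eye_dir}")

    module = tuple(f"G{i:03d}" for i in range(15))
    edges, mod = generate_network(
        NetworkSpec(n_genes=500, background_edge_prob=0.05,
                    planted_module=module, module_weight_multiplier=5.0,
                    seed=derive_seed(args.seed, "network"))
    )
    write_edges_tsv(out_dir / "network_edges.tsv", edges)
    write_gene_list(out_dir / "module_genes.txt", mod)
    print(f"wrote {len(edges)}-edge network with a {len(mod)}-gene planted module")

    universe, candidates = generate_universe(
        UniverseSpec(seed=derive_seed(args.seed, "universe"))
    )
    write_universe_tsv(out_dir / "universe.tsv", universe)
    write_gene_list(out_dir / "candidate_genes.txt", candidates)
    print(
        f"wrote universe of {len(universe)} genes "
        f"({int(universe['annotated'].sum())} annotated) "
        f"and {len(candidates)} candidates"
    )


if __name__ == "__main__":
    main()
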