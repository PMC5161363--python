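#!/usr/bin/env python
"""One-command driver for the full-scale screen.

Runs the complete pipeline: Q-screen of all 19683 three-node topologies for
the learning and the recall sub-function (10^4 Latin-hypercube parameter sets
each), selection of the robust pools (Q > 0.007 / Q > 0.008), enumeration of
all logically possible one-, two- and three-node combinations, the combined
Pavlovian screen, and the regulation-entropy comparison against random
networks.  At full scale this is a multi-core, multi-day computation — use
--workers to spread it over CPUs, or --limit/--n-sets for a scaled-down
smoke run.

    python scripts/full_scale.py --out results/full --workers 32
    python scripts/full_scale.py --out scratch/smoke --limit 30 --n-sets 5
"""

from __future__ import annotations

import argparse
import json
import sys
import time
from pathlib import Path

from joblib import Parallel, delayed

from pavnet.analysis import pool_entropy, random_network_baseline
from pavnet.cli_io import (
    RunConfig,
    fixture_zhang_network,
    screen_module,
    write_pool_json,
    write_qresults_tsv,
)
from pavnet.combination import compute_q_combined, enumerate_combinations
from pavnet.evaluation import select_pool
from pavnet.topology import LEARNING_ROLES, RECALL_ROLES, decode_id


def main(argv=None) -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--out", required=True, help="output directory")
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--n-sets", type=int, default=10_000)
    ap.add_argument("--combined-n-sets", type=int, default=None,
                    help="parameter sets per combined network (default: --n-sets)")
    ap.add_argument("--workers", type=int, default=1)
    ap.add_argument("--limit", type=int, default=None,
                    help="screen only the first N topologies (smoke runs)")
    args = ap.parse_args(argv)

    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)
    cfg = RunConfig(n_sets=args.n_sets, seed=args.seed, n_workers=args.workers)
    n_comb = args.combined_n_sets or args.n_sets
    summary: dict = {"seed": args.seed, "n_sets": args.n_sets}
    t0 = time.time()

    pools = {}
    for function, threshold, roles in (
        ("learning", cfg.q_threshold_learning, LEARNING_ROLES),
        ("recall", cfg.q_threshold_recall, RECALL_ROLES),
    ):
        print(f"[{time.time() - t0:8.0f}s] screening {function} module ...",
              file=sys.stderr, flush=True)
        results = screen_module(
            function, args.n_sets, args.seed, cfg,
            limit=args.limit, n_workers=args.workers,
        )
        write_qresults_tsv(results, out / f"{function}.qvalues.tsv")
        pool = select_pool(results, threshold)
        write_pool_json(pool, function, threshold, out / f"{function}.pool.json")
        pools[function] = [decode_id(i, 3, roles) for i, _q in pool]
        summary[f"n_robust_{function}"] = len(pool)

    top_q = 0.0
    zhang = fixture_zhang_network()
    zhang_q = None
    for arity in (1, 2, 3):
        combos = list(
            enumerate_combinations(pools["learning"], pools["recall"], arity)
        )
        summary[f"n_combinations_arity{arity}"] = len(combos)
        print(f"[{time.time() - t0:8.0f}s] screening {len(combos)} "
              f"arity-{arity} combinations ...", file=sys.stderr, flush=True)
        qres = Parallel(n_jobs=args.workers)(
            delayed(compute_q_combined)(c, n_comb, args.seed, cfg.settings)
            for c in combos
        )
        rows = sorted(
            (
                (c.learning_id, c.recall_id,
                 ";".join(f"{a}-{b}" for a, b in sorted(c.merge.pairs)),
                 arity, c.added_memory_edge, r.n_sets, r.n_pass, r.q)
                for c, r in zip(combos, qres)
            )
        )
        import pandas as pd

        pd.DataFrame(
            rows,
            columns=["learning_id", "recall_id", "merge_map", "arity",
                     "added_memory_edge", "n_sets", "n_pass", "q"],
        ).to_csv(out / f"combined.arity{arity}.tsv", sep="\t", index=False)
        summary[f"n_functional_arity{arity}"] = sum(r.n_pass > 0 for r in qres)
        if qres:
            top_q = max(top_q, max(r.q for r in qres))
        for c, r in zip(combos, qres):
            same_graph = (
                c.arity == zhang.arity
                and c.topology.adjacency.tobytes() == zhang.topology.adjacency.tobytes()
            )
            if same_graph and zhang_q is None:
                zhang_q = r.q
    summary["top_pavlovian_q"] = top_q
    if zhang_q is None:
        zq = compute_q_combined(zhang, n_comb, args.seed, cfg.settings)
        zhang_q = zq.q
    summary["zhang_design_q"] = zhang_q

    combined5 = [
        c.topology
        for c in enumerate_combinations(pools["learning"], pools["recall"], 1)
    ]
    if combined5:
        summary["entropy_combined_arity1"] = pool_entropy(combined5).mean
    summary["entropy_random_5node"] = random_network_baseline(5, 100, args.seed).mean

    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    print(json.dumps(summary, indent=2))
    return 0


if __name__ == "__main__":
    raise SystemExit(main())
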