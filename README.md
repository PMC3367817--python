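# dsdmc

A compiler and probabilistic verifier for two-domain DNA strand
displacement (DSD) systems.  It parses DSD-style programs describing
strands and gates, derives the induced chemical reaction network under the
merged ("infinite") reduction semantics — toehold binding is rate-limiting,
all downstream unbinding/displacement steps are instantaneous, and gates
are identified up to branch migration — builds the population-level
continuous-time Markov chain, and answers correctness, reliability and
performance queries: deadlock analysis with counterexample paths,
unbounded and time-bounded reachability probabilities, expected
completion times, and absorption distributions.

The bundled gate library contains executable builders for the classic
two-domain case studies: the signal transducer (including the crosstalk
bug caused by a shared recognition domain and its fix by an extra `new`
restriction), catalyst gates with and without garbage collection, and an
approximate-majority voting circuit assembled from four constant-fuel
catalysts.  The builders reproduce the published analyses exactly: the
faulty transducer pair has two deadlock states with a 0.5/0.5 split
between error and success, the reachable state spaces match the published
counts (57 188 / 284 641 / 1 160 292 states for N = 4, 5, 6 transducer
copies; 240 286 states for the X=3, Y=5 majority model), and the
consensus-probability table is reproduced to four decimals.

## Layout

| module        | contents |
| ------------- | -------- |
| `dsd_core`    | domains/strands/gates data model, parser, printer, canonicalization (rotation + branch-migration normal form), module expansion, well-formedness |
| `reduction`   | elementary reduction rules (RB/RU/RC/RM/RD), merged reaction semantics, unproductive-binding filter |
| `network`     | species-closure reaction network generation, reactivity classification, serialization |
| `ctmc`        | population CTMC construction, labels (`strands_reactive`, `gates_reactive`, `output*`, `all_done`), rewards, explicit-state export |
| `checking`    | deadlock/CTL checks, reachability probabilities (prob-0/1 precomputation + Gauss–Seidel), uniformization, expected rewards, absorption distributions |
| `simulate`    | Gillespie simulation used as an independent oracle |
| `gate_library`| case-study builders and the synthetic fixture generator |
| `cli_io`      | `dsdmc` command line interface |

## CLI

```sh
# compile a DSD program to its reaction network
dsdmc compile program.dsd

# build the CTMC, run queries from a JSON file
dsdmc ctmc program.dsd
dsdmc check program.dsd queries.json --config config.json

# stochastic simulation, explicit-state export, case studies
dsdmc simulate program.dsd --seed 7 --out traj.csv
dsdmc export-prism program.dsd model_prefix
dsdmc casestudy transducer -n 1
dsdmc casestudy approx-majority --x0 2 --y0 1
```

The textual dialect: `<t^ x>` upper strand, `{...}` lower strand,
`{L'}<L>[S]<R>{R'}` gate segments joined by `:` (shared lower strand) or
`::` (shared upper strand), `^` toehold marker, `*` complement, `|`
parallel composition, `N * D` populations, `constant D` held-constant
populations, `new n D` domain restriction and `def X(a,b) = D` modules.

A query file is a JSON list of objects such as

```json
[{"type": "prob_reach", "predicate": "deadlock & ~all_done"},
 {"type": "prob_reach_within", "predicate": "all_done", "T": 20000},
 {"type": "expected_time", "predicate": "all_done"}]
```

with predicates written as vectorized expressions over the label names.

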