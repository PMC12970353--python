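# bedcrypt

Privacy-preserving BED interval analytics. A client preprocesses a database
track *B* into four per-chromosome signal arrays (coverage prefix sum, start
prefix sum, end prefix sum, per-base depth), concatenates them into a global
vector, chunks the vector to the SIMD batching capacity, permutes chunk order
with a client-secret Fisher–Yates shuffle, and encrypts each chunk under BFV.
The server hosts only ciphertext chunks and answers every query with one
fixed kernel per requested scalar — a slot rotation followed by a plaintext
unit-mask multiplication — so it learns neither the data, nor the queried
loci, nor which operation a request serves. The client decrypts the returned
scalars and reassembles bedtools-style outputs for five operations:
`coverage`, `intersect` (`-u`/`-v`), `window` (`-c`/`-u`/`-v`, margin `-w`),
`depth`, and `jaccard`.

Two interchangeable HE backends sit behind one interface:

* **`bfv`** — a real lattice implementation (pure NumPy): RNS coefficient
  arithmetic over NTT-friendly word-sized primes, SIMD batching with the
  two-row slot layout, Galois rotations with hybrid key switching through
  special primes, and exact invariant-noise-budget measurement. Defaults:
  ring dimension N = 8192, 30-bit batching-prime plaintext modulus, 218-bit
  default coefficient modulus chain at the 128-bit security level. No
  ciphertext–ciphertext multiplication and no relinearization anywhere.
* **`mock`** — plaintext vectors with a calibrated noise ledger
  (fresh 136 bits, −3 per rotation, −35 per mask), for fast pipeline tests
  without lattice arithmetic.

## CLI

```sh
bedcrypt keygen -o keys/ --backend bfv --seed 1
bedcrypt build-db -b B.bed -g genome.txt -k keys/ -o store/
bedcrypt query --op coverage  -a A.bed -g genome.txt -k keys/ --db store/
bedcrypt query --op window --mode c --window 5 -a A.bed -g genome.txt -k keys/ --db store/
bedcrypt refresh -b B.bed -g genome.txt -k keys/ -o store/ --seed 99
bedcrypt bench --op jaccard --backend mock --out bench.json
```

`genome.txt` holds `chrom<TAB>length` lines; BED inputs are 0-based
half-open, three or more tab-separated columns. A server can also be run
out of process: `bedcrypt serve --db store/ -k keys/ --transport tcp` (or a
filesystem mailbox with `--transport dir --mailbox M/`), and queried with
`bedcrypt query ... --host H --port P` (or `--mailbox M/`). The store
directory contains only ciphertext chunks and public parameters; the layout
manifest, permutation map, and secret key stay in the key directory and must
never be uploaded.

### Output dialects

* `coverage`: `chrom start end overlap_count covered_bases length fraction`
  (fractions printed with 7 significant digits).
* `intersect`/`window` `-u`/`-v`: the original A interval; `-c` appends the
  overlap count. Emitted coordinates are always the unexpanded A interval.
* `depth`: `chrom pos depth`, 0-based, interval-major (local dialect).
* `jaccard`: header plus `intersection union jaccard` (no `n_intersections`;
  the boundary reads cannot produce it by design).

## Notes

* The synthetic-data module (`bedcrypt.synth`) generates seeded BED
  workloads and contains the brute-force per-base/pairwise oracle used as
  ground truth throughout the test suite; it shares no interval arithmetic
  with the production modules.
* Bench reports (time / peak RSS / bytes / noise trace) are measured, never
  asserted against reference hardware.
* The streaming server keeps a bounded chunk cache (4 chunks), so peak
  memory is independent of database size and request length; the bench
  memory cap documented for the 10^3-selector batch test is 512 MB.
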