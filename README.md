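# crmkit

Discovery of **common cis-regulatory modules (CRMs)** in gene batteries.

A CRM here is an ordered, strand-oriented, non-overlapping cluster of
transcription-factor binding sites (TFBSs) on a promoter, written as a
label like `+NFKB__-CREB__-SP1F`. Given per-promoter TFBS annotations
(with multiple alternative promoters per gene), expression-pattern
assignments and pathway gene sets, crmkit:

1. builds **gene batteries** — intersections of an expression pattern
   with a pathway enriched in it (hypergeometric, p < 0.05);
2. searches each battery for **common CRMs** by breadth-first
   combination of the individually common oriented TFBSs, treating a
   module present on *any* alternative promoter of a gene as present for
   that gene, and requiring a length-consistent instance (span within
   half-to-double of the module's average instance span) in at least
   `ceil(delta * N)` of the N battery genes (delta = 0.7 by default);
3. scores each common CRM against a background gene set with the
   **hypergeometric upper-tail p-value** and calibrates battery-size
   dependent significance thresholds by randomized draws from the
   background (a fixed 0.01 threshold is used for batteries of 14+
   genes);
4. **decomposes** significant CRMs into transcription factors and
   reports factors recurring in at least three batteries as critical
   regulators, exporting a factor-to-gene regulatory edge list.

A seeded synthetic-data module generates promoter profiles, backgrounds
and pattern/pathway fixtures with planted modules and a machine-readable
truth record, so the entire pipeline is testable offline.

## File formats

All coordinates are **TSS-relative signed integers** (negative =
upstream) with inclusive `[start, end]` intervals; the default promoter
region is −500..+100. Converting half-open 0-based GFF coordinates is
supported via `crmkit.profiles.gff_to_tss_relative`.

- site table: TSV `gene_id  promoter_id  factor_id  start  end  strand`
- gene sets: GMT (`name  description  member...`)
- pattern assignments: TSV `gene_id  pattern`
- calibration table: TSV `N  threshold` with a `#` metadata header
- promoter FASTA for the optional PWM scanner: headers like
  `>PROM1 gene_id=G1 offset=-500` (offset = TSS-relative coordinate of
  the first base)

## CLI

```sh
# generate a synthetic scenario with planted modules
crmkit simulate --seed 1 --out scenario/ --module '+NFKB__-CREB__-SP1F'

# battery construction, CRM search, calibration
crmkit batteries --patterns scenario/patterns.tsv --pathways scenario/pathways.gmt \
    --universe scenario/universe.txt --out batteries.tsv
crmkit search --sites scenario/sites.tsv --delta 0.7 --max-size 3 \
    --score --background scenario/background_sites.tsv --out crms.tsv
crmkit calibrate --background scenario/background_sites.tsv --seed 1 \
    --reps 100 --sizes 4-20 --out thresholds.tsv

# full pipeline from a YAML config (sites/patterns/pathways/universe/
# background paths plus alpha or thresholds)
crmkit run --config pipeline.yaml --out results/

# optional: scan promoter FASTA with PWMs into a site table
crmkit scan --fasta promoters.fa --pwms matrices.pwm --out sites.tsv
```

Every stochastic subcommand takes `--seed` and is exactly reproducible
for a fixed seed. Logs go to stderr; data only to files.

## Package layout

- `crmkit.profiles` — binding sites, promoter/gene profiles, oriented-key
  index, minimal-span instance matching, site-table IO
- `crmkit.crm_search` — breadth-first common-CRM search with
  anti-monotone pruning, length band, report IO
- `crmkit.significance` — hypergeometric scoring, background hit counts,
  randomized threshold calibration
- `crmkit.batteries` — pattern x pathway enrichment and battery assembly
- `crmkit.tf_inference` — CRM decomposition, critical-TF rule, edge list
- `crmkit.synthetic_data` — seeded generators with planted truth
- `crmkit.cli_io` — click CLI, pipeline driver, PWM scanner
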