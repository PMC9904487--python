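{
  "final_window": [
    "HB-chr1-20"
  ],
  "inputs": {
    "haplotypes": {
      "path": "/tmp/pytest-of-root/pytest-7/simdata0/haplotypes.tsv",
      "sha256": "adccffb57a21808fa22e499a1f0e0f1dbb74190b53fcfc35c3de1a13f6e4fd6e"
    },
    "map": {
      "path": "/tmp/pytest-of-root/pytest-7/simdata0/map.tsv",
      "sha256": "e5ccb7d609e577c5bd34a70348b7f50c3ee4717766d4004bce395d02ac1c51ee"
    },
    "panel": {
      "path": "/tmp/pytest-of-root/pytest-7/simdata0/panel.tsv",
      "sha256": "58b23cdf0d1ad126e527424109604e299386c71b390df59e581f0635fae4663d"
    },
    "pedigree": {
      "path": "/tmp/pytest-of-root/pytest-7/simdata0/pedigree.tsv",
      "sha256": "6926603ff49beba90b665064a362585fc520b5da0fcb965de0790bce8d502c47"
    }
  },
  "parameters": {
    "bridge_missing": 0,
    "chromosome": "chr1",
    "haplotypes_path": "/tmp/pytest-of-root/pytest-7/simdata0/haplotypes.tsv",
    "locus_name": "L1",
    "map_path": "/tmp/pytest-of-root/pytest-7/simdata0/map.tsv",
    "out_dir": "out",
    "panel_path": "/tmp/pytest-of-root/pytest-7/simdata0/panel.tsv",
    "pedigree_path": "/tmp/pytest-of-root/pytest-7/simdata0/pedigree.tsv",
    "pos_end": null,
    "pos_start": 16000000,
    "reported_path": null,
    "threshold": null,
    "triage": false
  },
  "placement": {
    "anchor_hbs": [
      "HB-chr1-20"
    ],
    "kind": "WITHIN"
  },
  "tool": "haploseer",
  "validation_accuracy": null,
  "version": "0.1.0"
}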