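{
 "schema_version": "v1",
 "features": [
  {
   "name": "seed_canonical_2_7",
   "type": "bool",
   "description": "exact WC consecutive pairing of miRNA 2-7"
  },
  {
   "name": "seed_canonical_3_8",
   "type": "bool",
   "description": "exact WC consecutive pairing of miRNA 3-8"
  },
  {
   "name": "seed_noncanonical_2_7",
   "type": "bool",
   "description": "window 2-7 pairs with GU allowed and at most one defect"
  },
  {
   "name": "seed_noncanonical_3_8",
   "type": "bool",
   "description": "window 3-8 pairs with GU allowed and at most one defect"
  },
  {
   "name": "wc_count_r1_8",
   "type": "int",
   "description": "Watson-Crick pairs in miRNA region 1-8"
  },
  {
   "name": "gu_count_r1_8",
   "type": "int",
   "description": "GU wobble pairs in miRNA region 1-8"
  },
  {
   "name": "unpaired_count_r1_8",
   "type": "int",
   "description": "unpaired miRNA positions in miRNA region 1-8"
  },
  {
   "name": "wc_count_r9_12",
   "type": "int",
   "description": "Watson-Crick pairs in miRNA region 9-12"
  },
  {
   "name": "gu_count_r9_12",
   "type": "int",
   "description": "GU wobble pairs in miRNA region 9-12"
  },
  {
   "name": "unpaired_count_r9_12",
   "type": "int",
   "description": "unpaired miRNA positions in miRNA region 9-12"
  },
  {
   "name": "wc_count_r13_0",
   "type": "int",
   "description": "Watson-Crick pairs in miRNA region 13-0"
  },
  {
   "name": "gu_count_r13_0",
   "type": "int",
   "description": "GU wobble pairs in miRNA region 13-0"
  },
  {
   "name": "unpaired_count_r13_0",
   "type": "int",
   "description": "unpaired miRNA positions in miRNA region 13-0"
  },
  {
   "name": "duplex_score",
   "type": "int",
   "description": "total duplex DP score"
  },
  {
   "name": "paired_total",
   "type": "int",
   "description": "number of paired miRNA positions"
  },
  {
   "name": "site_freq_A",
   "type": "float",
   "description": "site A mononucleotide frequency"
  },
  {
   "name": "site_freq_C",
   "type": "float",
   "description": "site C mononucleotide frequency"
  },
  {
   "name": "site_freq_G",
   "type": "float",
   "description": "site G mononucleotide frequency"
  },
  {
   "name": "site_freq_U",
   "type": "float",
   "description": "site U mononucleotide frequency"
  },
  {
   "name": "site_difreq_AA",
   "type": "float",
   "description": "site AA dinucleotide frequency"
  },
  {
   "name": "site_difreq_AC",
   "type": "float",
   "description": "site AC dinucleotide frequency"
  },
  {
   "name": "site_difreq_AG",
   "type": "float",
   "description": "site AG dinucleotide frequency"
  },
  {
   "name": "site_difreq_AU",
   "type": "float",
   "description": "site AU dinucleotide frequency"
  },
  {
   "name": "site_difreq_CA",
   "type": "float",
   "description": "site CA dinucleotide frequency"
  },
  {
   "name": "site_difreq_CC",
   "type": "float",
   "description": "site CC dinucleotide frequency"
  },
  {
   "name": "site_difreq_CG",
   "type": "float",
   "description": "site CG dinucleotide frequency"
  },
  {
   "name": "site_difreq_CU",
   "type": "float",
   "description": "site CU dinucleotide frequency"
  },
  {
   "name": "site_difreq_GA",
   "type": "float",
   "description": "site GA dinucleotide frequency"
  },
  {
   "name": "site_difreq_GC",
   "type": "float",
   "description": "site GC dinucleotide frequency"
  },
  {
   "name": "site_difreq_GG",
   "type": "float",
   "description": "site GG dinucleotide frequency"
  },
  {
   "name": "site_difreq_GU",
   "type": "float",
   "description": "site GU dinucleotide frequency"
  },
  {
   "name": "site_difreq_UA",
   "type": "float",
   "description": "site UA dinucleotide frequency"
  },
  {
   "name": "site_difreq_UC",
   "type": "float",
   "description": "site UC dinucleotide frequency"
  },
  {
   "name": "site_difreq_UG",
   "type": "float",
   "description": "site UG dinucleotide frequency"
  },
  {
   "name": "site_difreq_UU",
   "type": "float",
   "description": "site UU dinucleotide frequency"
  },
  {
   "name": "site_au_content",
   "type": "float",
   "description": "site A+U fraction"
  },
  {
   "name": "site_gc_content",
   "type": "float",
   "description": "site G+C fraction"
  },
  {
   "name": "site_length",
   "type": "int",
   "description": "site length in nt"
  },
  {
   "name": "site_rel_position",
   "type": "float",
   "description": "site offset / (UTR length - site length); 0 without context"
  },
  {
   "name": "mirna_freq_A",
   "type": "float",
   "description": "miRNA A mononucleotide frequency"
  },
  {
   "name": "mirna_freq_C",
   "type": "float",
   "description": "miRNA C mononucleotide frequency"
  },
  {
   "name": "mirna_freq_G",
   "type": "float",
   "description": "miRNA G mononucleotide frequency"
  },
  {
   "name": "mirna_freq_U",
   "type": "float",
   "description": "miRNA U mononucleotide frequency"
  },
  {
   "name": "mirna_gc_content",
   "type": "float",
   "description": "miRNA G+C fraction"
  },
  {
   "name": "mirna_length",
   "type": "int",
   "description": "miRNA length in nt"
  }
 ]
}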