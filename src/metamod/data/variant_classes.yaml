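# Variant-classification vocabulary used to decide whether a mutation call is
# protein-altering ("nonsilent").  Matching is case-insensitive and ignores
# underscores, spaces and punctuation, so "Missense_Mutation", "missense
# mutation" and "MISSENSE-MUTATION" all resolve to the same class.
#
# Edit this file (or point MetamodConfig at a copy) to extend the synonym
# table for other MAF dialects; tokens not listed anywhere are treated as
# silent and tallied in the log.
nonsilent:
  missense:
    - Missense_Mutation
    - Missense
  frameshift:
    - Frame_Shift_Del
    - Frame_Shift_Ins
    - Frameshift_Deletion
    - Frameshift_Insertion
    - Frameshift
  nonsense:
    - Nonsense_Mutation
    - Nonsense
  nonstop:
    - Nonstop_Mutation
    - Nonstop
  splice_site:
    - Splice_Site
  translation_start_site:
    - Translation_Start_Site
    - Start_Codon_SNP
    - Start_Codon_Del
    - Start_Codon_Ins
silent:
  - Silent
  - Synonymous
  - 3'UTR
  - 5'UTR
  - 3'Flank
  - 5'Flank
  - Intron
  - IGR
  - RNA
  - Splice_Region
  - lincRNA
  - Targeted_Region
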