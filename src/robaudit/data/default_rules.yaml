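# Default keyword rules and synthetic support-text templates for the
# random-sequence-generation support classifier.
#
# Matching model: the support text is whitespace-normalised and rules are
# applied tier by tier (high-risk indicators, then explicit low-risk methods,
# then not-described subcategories); within a tier, rules run in canonical
# report row order and the first rule whose every `all` pattern matches (and
# no `none` pattern matches) wins.  Patterns are case-insensitive regular
# expressions searched anywhere in the text.  A comment matching no rule at
# all falls back to NOT_DESCRIBED.
#
# Negation is deliberately not modelled ("no computer was used" matches the
# computer rule); see the package methods note.
#
# Edit and pass via --rules to audit the effect of rule changes; `version`
# distinguishes rule changes from data changes in downstream reports.

version: "1.0"

tiers:
  - name: high
    rules:
      - category: QUASI_RANDOM
        all:
          - '\balternat(e|ed|ely|ion|ing)\b|date of birth|birth ?date|record number|chart number|case number|hospital number|day of (admission|the week|presentation)|admission (date|day|order)|odd or even|odd/even|\bquasi[- ]?random'
      - category: INCOMPLETE_ERRONEOUS
        all:
          - 'incomplete|erroneous|\bpartial(ly)? randomi[sz]|randomi[sz]ation (was )?(flawed|failed|broken)|error in (the )?randomi[sz]|not all (participants|patients) (were )?randomi[sz]ed'
      - category: JUDGMENT_PREFERENCE_AVAILABILITY
        all:
          - "judge?ment of (the )?(physician|clinician|doctor|investigator)|(physician|clinician|investigator)'?s? judge?ment|at the discretion|discretion of|preference of|(patient|participant|subject) preference|according to (the )?availability|availability of (the )?(intervention|treatment|drug)"

  - name: low
    rules:
      - category: RANDOM_NUMBER_TABLE
        all:
          - 'random[- ]number table|random[- ]numbers table|table of random numbers|random[- ]digit table'
      - category: COMPUTER_SOFTWARE_GENERATED
        all:
          - 'computer|software|\bprogram|electronic|\bexcel\b|\bsas\b|\bspss\b|\bstata\b|\bralloc\b'
      - category: IVRS
        all:
          - '\bivrs\b|interactive voice|voice[- ]response'
      - category: MINIMISATION
        all:
          - 'minimi[sz]ation|minimi[sz]ed allocation'
      - category: RNG_NO_COMPUTER
        all:
          - 'random[- ]number generat(or|ion)'
      - category: WEB_BASED
        all:
          - 'https?://|\bwww\.|\bweb[- ]?based|\bwebsite\b|\bweb page|\bonline\b|\binternet\b'
      - category: COIN_TOSSING
        all:
          - '\bcoin\b'
      - category: DRAWING_LOTS
        all:
          - '\blots?\b|\blottery\b'
      - category: SHUFFLING_CARDS_ENVELOPES
        all:
          - '\bcard(s)?\b|envelope|\bhat\b'
          - 'shuffl|\bdraw(n|ing)?\b|\bdrew\b|toss|\bpick(ed)?\b|\bmix(ed|ing)?\b'
      - category: THROWING_DICE
        all:
          - '\bdice\b|\bdie\b'

  - name: not_described
    rules:
      - category: NOT_DESCRIBED
        all:
          - 'no information|not described|not stated|not reported|unreported|not mentioned|no details|insufficient (detail|information)|not specified|\bassumed\b|same as above|\bas above\b|see previous|\bappendix\b|\bconsort\b|translation required|trial was stopped|not adequately designed|withdrawn prior|described as randomi[sz]ed'
      - category: BLOCK_OR_STRATIFICATION_ONLY
        all:
          - '\bblock(s|ed)?\b|stratif'
      - category: ENVELOPES_NO_METHOD
        all:
          - 'envelope'
        none:
          - 'shuffl|\bdraw(n|ing)?\b|\bdrew\b|toss|\bdice\b'
      - category: CENTRAL_RANDOMISATION_NO_METHOD
        all:
          - '\bcentral(ly)?\b|statistic(s|al) (department|unit|center|centre)|pharmacy|third party|coordinating cent(er|re)|telephone'
      - category: BASELINE_IMBALANCE
        all:
          - 'baseline|between (the )?groups'
          - 'imbalanc|\bdiffered\b|not comparable|unbalanc|unequal'
      - category: BASELINE_BALANCE
        all:
          - 'baseline|between (the )?groups'
          - '\bbalanc|comparable|similar|well[- ]matched|no significant difference'

# Support-text templates used by the synthetic corpus generator; every
# template must classify back to its own category (round-trip invariant).
templates:
  RANDOM_NUMBER_TABLE:
    - "Randomised using a random number table."
    - "Quote: 'allocation based on a table of random numbers'."
    - "A random numbers table was used to generate the sequence."
  COMPUTER_SOFTWARE_GENERATED:
    - "Computer generated randomisation list."
    - "Randomisation sequence generated by statistical software."
    - "Computer random number generator was used."
  IVRS:
    - "Allocation via interactive voice response system."
    - "Central IVRS used for randomisation."
    - "Randomisation by IVRS."
  MINIMISATION:
    - "Minimisation algorithm balancing age and sex."
    - "Allocation by minimization."
    - "Minimisation with a random element."
  RNG_NO_COMPUTER:
    - "A random number generator was used."
    - "Quote: 'using a random number generator'."
    - "Sequence obtained from a random number generator."
  WEB_BASED:
    - "Randomisation via a web-based system."
    - "Online randomisation at http://example.org."
    - "Allocated through an internet randomisation service."
  COIN_TOSSING:
    - "Allocation by coin toss."
    - "A coin was flipped for each participant."
    - "Coin tossing."
  DRAWING_LOTS:
    - "Drawing of lots."
    - "Allocation determined by lot."
    - "Lots were drawn from a box."
  SHUFFLING_CARDS_ENVELOPES:
    - "Shuffled sealed envelopes."
    - "Cards were shuffled and drawn."
    - "Envelopes were shuffled before allocation."
  THROWING_DICE:
    - "Allocation by throwing dice."
    - "A die was rolled to allocate participants."
    - "Dice throw determined the allocation."
  QUASI_RANDOM:
    - "Participants were allocated by alternation."
    - "Randomised by date of birth."
    - "Allocation according to hospital record number."
  INCOMPLETE_ERRONEOUS:
    - "Randomisation was incomplete."
    - "Erroneous randomisation procedure."
    - "Only partially randomised."
  JUDGMENT_PREFERENCE_AVAILABILITY:
    - "Allocation according to the physician's judgement."
    - "Treatment assigned by patient preference."
    - "Allocation based on availability of the intervention."
  NOT_DESCRIBED:
    - "Not stated."
    - "No information available."
    - "Method of randomisation not described."
    - "Not reported."
  BLOCK_OR_STRATIFICATION_ONLY:
    - "Block randomisation."
    - "Stratified by centre."
    - "Permuted blocks of four were used."
  ENVELOPES_NO_METHOD:
    - "Sealed opaque envelopes."
    - "Sequentially numbered envelopes were used."
    - "Allocation by envelopes."
  CENTRAL_RANDOMISATION_NO_METHOD:
    - "Central randomisation by the statistics department."
    - "Randomised by the central pharmacy."
    - "Allocation performed by an independent third party."
  BASELINE_IMBALANCE:
    - "Baseline characteristics differed between groups."
    - "Marked baseline imbalance between the groups."
    - "Groups were not comparable at baseline."
  BASELINE_BALANCE:
    - "Baseline characteristics were balanced between groups."
    - "Groups were comparable at baseline."
    - "No significant difference in baseline characteristics."
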