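# Cross-cycle difference bounds, by check-type alias.  A difference within
# [lower, upper] (inclusive) aligns the current issue with its predecessor;
# outside, a difference-investigation issue is opened.
default_percentage: [-10, 10]
default_count: [0, 0]
per_alias:
  MissData: [-10, 10]
  MissConceptID: [-10, 10]
  MissVisitFact: [-10, 10]
  MissVisitLink: [-10, 10]
  UnexMiss: [-10, 10]
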