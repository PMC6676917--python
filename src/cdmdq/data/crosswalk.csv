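source_concept_id,target_concept_id,status
44820000,441000,valid
44820001,441001,valid
44820002,441002,valid
44820003,441003,valid
44820004,441004,valid
44820005,441005,valid
44820006,441006,valid
44820007,441007,valid
44820008,441008,valid
44820009,441009,deprecated
44820010,441010,deprecated
44820011,441011,deprecated
44920000,1125000,valid
44920001,1125001,valid
44920002,1125002,valid
44920003,1125003,valid
44920004,1125004,valid
44920005,1125005,valid
44920006,1125006,valid
44920007,1125007,valid
44930000,2100000,valid
44930001,2100001,valid
44930002,2100002,valid
44930003,2100003,valid
44930004,2100004,valid
44940000,3000000,valid
44940001,3000001,valid
44940002,3000002,valid
44940003,3000003,valid
44940004,3000004,valid
44940005,3000005,valid
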