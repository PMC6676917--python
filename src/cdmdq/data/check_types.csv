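alias,name,method_category,harmonized_category,scope,result_kind,reconstructed
MissData,missing or unpopulated values,element_presence,completeness,field,percentage,0
MissConceptID,missing or unmapped concept identifier,element_presence,completeness,field,percentage,0
MissFact,persons lacking an expected fact,element_presence,completeness,field,count,0
MissVisitFact,visits without clinical facts,element_presence,completeness,table,percentage,0
MissVisitLink,facts lacking an encounter link,element_presence,completeness,field,percentage,1
InconDateTime,inconsistent date and datetime,element_agreement,temporal_plausibility,field_pair,count,0
InconVisitType,inconsistent visit types across domains,element_agreement,atemporal_plausibility,cross_table,count,0
InconSource,inconsistent nullness of source value and concept,element_agreement,atemporal_plausibility,field_pair,count,0
ImplEvent,event start after event end,element_agreement,temporal_plausibility,field_pair,count,0
UnexDiff,unexpected change in record count between cycles,source_agreement,temporal_plausibility,table,percentage,0
UnexMiss,unexpected change in completeness between cycles,source_agreement,completeness,field,percentage,0
UnexTop,unexpected most frequent values,distribution_comparison,atemporal_plausibility,field,value_list,0
UnexTopSource,unexpected most frequent source values,distribution_comparison,atemporal_plausibility,field,value_list,1
UnexFact,unexpected concepts absent from reference inventories,distribution_comparison,atemporal_plausibility,field,value_list,0
TempOutlier,outlier months in longitudinal fact volume,distribution_comparison,temporal_plausibility,field,value_list,0
TempOutlierFact,outlier months in table-level fact volume,distribution_comparison,temporal_plausibility,table,value_list,1
InvalidConID,concept identifier absent from vocabulary,face_validity,value_conformance,field,count,0
InvalidVocab,concept from a vocabulary not allowed for the field,face_validity,value_conformance,field,count,0
InvalidValue,value outside the allowed value set,face_validity,value_conformance,field,count,0
InvalidMap,deprecated source-to-standard mapping,face_validity,value_conformance,field_pair,count,0
InvalidDomain,concept domain inconsistent with the field,face_validity,value_conformance,field,count,1
InconCohort,inclusion criteria violation,face_validity,atemporal_plausibility,table,count,0
ImplFutureDate,fact dated in the future,face_validity,temporal_plausibility,field,count,0
ImplPastDate,fact dated before the plausibility floor,face_validity,temporal_plausibility,field,count,0
ImplAge,fact dated at an implausible age,face_validity,temporal_plausibility,field,count,1
PreBirth,fact dated before birth,face_validity,temporal_plausibility,field_pair,count,0
PostDeath,fact dated after death,face_validity,temporal_plausibility,field_pair,count,0
NumOutlier,numeric value outside robust fences,face_validity,atemporal_plausibility,field,count,0
NumOutlierUnit,numeric value outside unit-stratified robust fences,face_validity,atemporal_plausibility,field,count,1
OrphanFact,fact relationship referencing a missing fact,face_validity,relational_conformance,cross_table,count,1
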