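item,symptom,component,cluster
it01,Sadness,DEPRESSION,DEPRESSION
it02,Elation,MANIA,MANIA
it03,Inner tension,DEPRESSION,ANXIETY
it04,Hostile feelings,ANXIETY,DEPRESSION
it05,Inability to feel,DEPRESSION,DEPRESSION
it06,Pessimistic thoughts,DEPRESSION,DEPRESSION
it07,Suicidal thoughts,DEPRESSION,DEPRESSION
it09,Worrying over trifles,DEPRESSION,DEPRESSION
it11,Phobias,DEPRESSION,DEPRESSION
it12,Rituals,PSYCHOSIS,PSYCHOSIS
it13,Indecision,DEPRESSION,DEPRESSION
it14,Lassitude,DEPRESSION,DEPRESSION
it15,Fatiguability,DEPRESSION,DEPRESSION
it16,Concentration difficulties,DEPRESSION,DEPRESSION
it17,Failing memory,DEPRESSION,DEPRESSION
it18,Reduced appetite,DEPRESSION,DEPRESSION
it19,Reduced sleep,ANXIETY,ANXIETY
it20,Increased sleep,ANXIETY,ANXIETY
it21,Reduced sexual interest,DEPRESSION,DEPRESSION
it22,Increased sexual interest,MANIA,MANIA
it23,Autonomic disturbances,ANXIETY,ANXIETY
it24,Aches and pains,ANXIETY,ANXIETY
it25,Muscular tension,DEPRESSION,ANXIETY
it26,Loss of sensation or movement,DEPRESSION,DEPRESSION
it27,Derealization,DEPRESSION,PSYCHOSIS
it28,Depersonalization,DEPRESSION,PSYCHOSIS
it29,Feeling controlled,PSYCHOSIS,PSYCHOSIS
it30,Disrupted thoughts,PSYCHOSIS,PSYCHOSIS
it31,Ideas of persecution,PSYCHOSIS,PSYCHOSIS
it32,Ideas of grandeur,MANIA,MANIA
it33,Delusional mood,PSYCHOSIS,PSYCHOSIS
it34,Ecstatic experiences,MANIA,MANIA
it36,Other delusions,PSYCHOSIS,PSYCHOSIS
it37,Commenting voices,PSYCHOSIS,PSYCHOSIS
it38,Other auditory hallucinations,PSYCHOSIS,PSYCHOSIS
it39,Visual hallucinations,PSYCHOSIS,PSYCHOSIS
it40,Other hallucinations,PSYCHOSIS,PSYCHOSIS
it41,Apparent sadness,DEPRESSION,DEPRESSION
it42,Elated mood,MANIA,MANIA
it45,Lack of appropriate emotion,RETARDATION,RETARDATION
it46,Autonomic disturbances (observed),ANXIETY,ANXIETY
it48,Distractibility,BEHAV_DISORG,BEHAV_DISORG
it49,Withdrawal,RETARDATION,RETARDATION
it50,Perplexity,BEHAV_DISORG,BEHAV_DISORG
it51,Blank spells,RETARDATION,RETARDATION
it53,Pressure of speech,MANIA,MANIA
it54,Reduced speech,RETARDATION,RETARDATION
it56,Flight of ideas,MANIA,MANIA
it57,Incoherent speech,BEHAV_DISORG,BEHAV_DISORG
it58,Perseveration,BEHAV_DISORG,BEHAV_DISORG
it59,Overactivity,MANIA,MANIA
it60,Slowness of movement,RETARDATION,RETARDATION
it61,Agitation,BEHAV_DISORG,BEHAV_DISORG
it62,Involuntary movements,ANXIETY,ANXIETY
it63,Muscular tension (observed),ANXIETY,ANXIETY
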