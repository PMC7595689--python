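Concha_L,Ethmoid
Concha_L,Lacrimal_L
Concha_L,Maxilla_L
Concha_L,Palatine_L
Concha_R,Ethmoid
Concha_R,Lacrimal_R
Concha_R,Maxilla_R
Concha_R,Palatine_R
Ethmoid,Frontal
Ethmoid,Lacrimal_L
Ethmoid,Lacrimal_R
Ethmoid,Maxilla_L
Ethmoid,Maxilla_R
Ethmoid,Nasal_L
Ethmoid,Nasal_R
Ethmoid,Palatine_L
Ethmoid,Palatine_R
Ethmoid,Sphenoid
Ethmoid,Vomer
Frontal,Lacrimal_L
Frontal,Lacrimal_R
Frontal,Maxilla_L
Frontal,Maxilla_R
Frontal,Nasal_L
Frontal,Nasal_R
Frontal,Parietal_L
Frontal,Parietal_R
Frontal,Sphenoid
Frontal,Zygomatic_L
Frontal,Zygomatic_R
Lacrimal_L,Maxilla_L
Lacrimal_R,Maxilla_R
Maxilla_L,Maxilla_R
Maxilla_L,Nasal_L
Maxilla_L,Palatine_L
Maxilla_L,Vomer
Maxilla_L,Zygomatic_L
Maxilla_R,Nasal_R
Maxilla_R,Palatine_R
Maxilla_R,Vomer
Maxilla_R,Zygomatic_R
Nasal_L,Nasal_R
Occipital,Parietal_L
Occipital,Parietal_R
Occipital,Sphenoid
Occipital,Temporal_L
Occipital,Temporal_R
Palatine_L,Palatine_R
Palatine_L,Sphenoid
Palatine_L,Vomer
Palatine_R,Sphenoid
Palatine_R,Vomer
Parietal_L,Parietal_R
Parietal_L,Sphenoid
Parietal_L,Temporal_L
Parietal_R,Sphenoid
Parietal_R,Temporal_R
Sphenoid,Temporal_L
Sphenoid,Temporal_R
Sphenoid,Vomer
Sphenoid,Zygomatic_L
Sphenoid,Zygomatic_R
Temporal_L,Zygomatic_L
Temporal_R,Zygomatic_R
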