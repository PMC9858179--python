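group	cas
G1	000079-20-9
G1	000078-83-1
G1	000554-12-1
G1	001534-08-3
G1	000109-60-4
G1	000623-42-7
G1	000137-32-6
G1	000110-19-0
G1	000868-57-5
G1	000820-71-3
G1	000106-36-5
G1	000123-86-4
G1	002432-51-1
G1	005271-38-5
G1	000540-42-1
G1	000123-92-2
G1	000624-41-9
G1	000628-63-7
G1	016630-66-3
G1	001191-16-8
G1	023747-45-7
G1	115051-66-6
G1	000142-92-7
G1	000470-82-6
G1	NID1
G1	000140-11-4
G1	007371-86-0
G1	000103-45-7
G2	000123-72-8
G2	000123-73-9
G2	000616-25-1
G2	017528-72-2
G2	000565-69-5
G2	000066-25-1
G3	068411-77-8
G3	000108-88-3
G3	018729-48-1
G3	000105-54-4
G4	NID2
G4	001565-75-9
G4	002040-07-5
G5	000100-42-5
G5	000591-23-1
G5	005441-52-1
G5	001193-81-3
G5	000464-49-3
G5	074367-33-2
G5	74367-31-0
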