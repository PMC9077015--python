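# Synthetic stand-in pathway list for the systems-pharmacology arm (234 KEGG-style names).
# Carries the documented overlap structure with the metabonomics pathway set; not a database export.
Aminoacyl-tRNA biosynthesis
Glycolysis/Gluconeogenesis
Glycine, serine and threonine metabolism
Valine, leucine and isoleucine biosynthesis
Arginine and proline metabolism
Pyruvate metabolism
Citrate cycle (TCA cycle)
Pentose phosphate pathway
Pentose and glucuronate interconversions
Fructose and mannose metabolism
Ascorbate and aldarate metabolism
Fatty acid biosynthesis
Fatty acid elongation
Fatty acid degradation
Synthesis and degradation of ketone bodies
Steroid biosynthesis
Primary bile acid biosynthesis
Steroid hormone biosynthesis
Oxidative phosphorylation
Purine metabolism
Pyrimidine metabolism
Alanine metabolism
Cysteine and methionine metabolism
Valine, leucine and isoleucine degradation
Lysine degradation
Lysine biosynthesis
Histidine metabolism
Tyrosine metabolism
Phenylalanine metabolism
Tryptophan metabolism
Phenylalanine, tyrosine and tryptophan biosynthesis
beta-Alanine metabolism
Taurine and hypotaurine metabolism
Phosphonate and phosphinate metabolism
Selenocompound metabolism
Cyanoamino acid metabolism
Glutathione metabolism
Starch and sucrose metabolism
Amino sugar and nucleotide sugar metabolism
Glycerolipid metabolism
Inositol phosphate metabolism
Glycerophospholipid metabolism
Ether lipid metabolism
Arachidonic acid metabolism
Linoleic acid metabolism
alpha-Linolenic acid metabolism
Sphingolipid metabolism
Glycosaminoglycan degradation
Glycosaminoglycan biosynthesis - keratan sulfate
Glycosaminoglycan biosynthesis - heparan sulfate
Glycosylphosphatidylinositol (GPI)-anchor biosynthesis
Glycosphingolipid biosynthesis - lacto and neolacto series
Glycosphingolipid biosynthesis - globo series
Glycosphingolipid biosynthesis - ganglio series
Butanoate metabolism
C5-Branched dibasic acid metabolism
One carbon pool by folate
Methane metabolism
Thiamine metabolism
Riboflavin metabolism
Vitamin B6 metabolism
Nicotinate and nicotinamide metabolism
Pantothenate and CoA biosynthesis
Biotin metabolism
Lipoic acid metabolism
Folate biosynthesis
Retinol metabolism
Porphyrin and chlorophyll metabolism
Terpenoid backbone biosynthesis
Nitrogen metabolism
Sulfur metabolism
Caffeine metabolism
Metabolism of xenobiotics by cytochrome P450
Drug metabolism - cytochrome P450
Drug metabolism - other enzymes
Biosynthesis of unsaturated fatty acids
ABC transporters
Ribosome
RNA degradation
RNA polymerase
Basal transcription factors
DNA replication
Spliceosome
Proteasome
Protein export
PPAR signaling pathway
Base excision repair
Nucleotide excision repair
Mismatch repair
Homologous recombination
Non-homologous end-joining
MAPK signaling pathway
ErbB signaling pathway
Wnt signaling pathway
Notch signaling pathway
Hedgehog signaling pathway
TGF-beta signaling pathway
VEGF signaling pathway
Jak-STAT signaling pathway
NF-kappa B signaling pathway
HIF-1 signaling pathway
FoxO signaling pathway
Calcium signaling pathway
Phosphatidylinositol signaling system
PI3K-Akt signaling pathway
mTOR signaling pathway
AMPK signaling pathway
Insulin signaling pathway
Insulin secretion
Glucagon signaling pathway
Adipocytokine signaling pathway
Oxytocin signaling pathway
GnRH signaling pathway
Estrogen signaling pathway
Progesterone-mediated oocyte maturation
Prolactin signaling pathway
Thyroid hormone synthesis
Thyroid hormone signaling pathway
Aldosterone synthesis and secretion
Renin-angiotensin system
Apoptosis
p53 signaling pathway
Cell cycle
Cellular senescence
Ferroptosis
Necroptosis
Autophagy - animal
Lysosome
Peroxisome
Phagosome
Endocytosis
Regulation of actin cytoskeleton
Focal adhesion
Adherens junction
Tight junction
Gap junction
ECM-receptor interaction
Cell adhesion molecules (CAMs)
Cytokine-cytokine receptor interaction
Chemokine signaling pathway
Neuroactive ligand-receptor interaction
Complement and coagulation cascades
Toll-like receptor signaling pathway
NOD-like receptor signaling pathway
RIG-I-like receptor signaling pathway
Cytosolic DNA-sensing pathway
Natural killer cell mediated cytotoxicity
Antigen processing and presentation
T cell receptor signaling pathway
B cell receptor signaling pathway
Fc epsilon RI signaling pathway
Fc gamma R-mediated phagocytosis
Leukocyte transendothelial migration
Intestinal immune network for IgA production
Hematopoietic cell lineage
Platelet activation
Long-term potentiation
Long-term depression
Retrograde endocannabinoid signaling
Glutamatergic synapse
Cholinergic synapse
Serotonergic synapse
GABAergic synapse
Dopaminergic synapse
Synaptic vesicle cycle
Regulation of lipolysis in adipocytes
Fat digestion and absorption
Carbohydrate digestion and absorption
Protein digestion and absorption
Vitamin digestion and absorption
Mineral absorption
Bile secretion
Gastric acid secretion
Pancreatic secretion
Salivary secretion
Proximal tubule bicarbonate reclamation
Collecting duct acid secretion
Vasopressin-regulated water reabsorption
Aldosterone-regulated sodium reabsorption
Endocrine and other factor-regulated calcium reabsorption
Cardiac muscle contraction
Vascular smooth muscle contraction
Adrenergic signaling in cardiomyocytes
cAMP signaling pathway
cGMP-PKG signaling pathway
Ras signaling pathway
Rap1 signaling pathway
Hippo signaling pathway
Sphingolipid signaling pathway
Phospholipase D signaling pathway
Neurotrophin signaling pathway
Melanogenesis
Circadian rhythm
Circadian entrainment
Olfactory transduction
Taste transduction
Phototransduction
Inflammatory mediator regulation of TRP channels
Osteoclast differentiation
Alcoholism
Morphine addiction
Nicotine addiction
Cocaine addiction
Amphetamine addiction
Alzheimer disease
Parkinson disease
Huntington disease
Amyotrophic lateral sclerosis (ALS)
Prion diseases
Non-alcoholic fatty liver disease (NAFLD)
Insulin resistance
Type II diabetes mellitus
Type I diabetes mellitus
Maturity onset diabetes of the young
Pathways in cancer
Transcriptional misregulation in cancer
Proteoglycans in cancer
MicroRNAs in cancer
Chemical carcinogenesis
Viral carcinogenesis
Colorectal cancer
Pancreatic cancer
Glioma
Thyroid cancer
Acute myeloid leukemia
Chronic myeloid leukemia
Basal cell carcinoma
Melanoma
Renal cell carcinoma
Bladder cancer
Prostate cancer
Endometrial cancer
Breast cancer
Small cell lung cancer
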